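6/KJhwQAAgDQAQAAAAAAAAwCAAAAAAAAowMAAAAAAAAGAAYAcAAAAAAAAACoAQAAAAAAAHUBAAAA
AAAAAAAAAHkBAAAAAAAAFwQAAAAAAADiBAAAAAAAAOQFAAAAAAAAVgUAAAAAAACtBQAAAAAAAHRh
YmxlIGJlZDYKIkJyb3dzZXIgRXh0ZW5zaWJsZSBEYXRhIgooCiAgICBzdHJpbmcgIGNocm9tOyAi
UmVmZXJlbmNlIHNlcXVlbmNlIGNocm9tb3NvbWUgb3Igc2NhZmZvbGQiCiAgICB1aW50ICAgIGNo
cm9tU3RhcnQ7ICJTdGFydCBwb3NpdGlvbiBpbiBjaHJvbW9zb21lIgogICAgdWludCAgICBjaHJv
bUVuZDsgIkVuZCBwb3NpdGlvbiBpbiBjaHJvbW9zb21lIgogICAgc3RyaW5nICBuYW1lOyAiTmFt
ZSBvZiBpdGVtIgogICAgdWludCAgICBzY29yZTsgIlNjb3JlIGZyb20gMC0xMDAwIgogICAgY2hh
clsxXSBzdHJhbmQ7ICIrIG9yIC0iCikKADUHAAAAAAAAAAAAAAAA8D8AAAAAAAAUQAAAAAAA8KlA
AAAAAAAmvUCRjMp4AAEAAAQAAAAIAAAAAgAAAAAAAAAAAAAAAAAAAAEAAgBjaHIxAAAAANAHAABj
aHIyAQAAALAEAAAeAAAAAAAAAHicNc+9bQJBEAXgMeZHz024gAN0+79bAW1AAAExGRIdQEQXliyn
BFiEiABRA/FVQMTAzaz0ku+t3t4REU04U85iPlsZ5Igxvc6O8/XRsoUpXvyXMxR3SAHVmx+crbCH
D1auV2x78YASdX7TIfr+bD3C6EzDvBROcLnG6O0Htqt4Rnaycu4S3bstFxRnZWbdIwp9+aca0evO
kYtLTwoDm3Tpn29vBlJYJK9Fw8WPFg4u6qcaxpsWHslmeeOP8aRFgC+Jp552BTojeJw1kD0SAUEQ
hWeX5KWcQUIt82dmNlBCpxAIEMgUR3AWJVEOwQEcwR2QqfJqdzroDr6vuvtVF0qpAWvI2qxXBxPg
rcNYFQR31q7IIiKkGlUjSra9iAQOtfzK9hJew6QpRo3Ylkr1Oq2wGjbU+cSV4l1mYZC0yauehDOZ
sIjB5lUfiqMIByMDP/KHcI9kJVSf8CRiCudl04TwKyIg8H4b6ky46GYRYaLOQhPORSRELw+xhDcR
NbyTFy4JL1k4jcgAlfoD4046DOCsaCQAAQAAAgAAAAAAAAAAAAAARwAAAAEAAACwBAAAowMAAAAA
AAAABAAAAAAAAAEAAgAAAAAARwAAAAAAAADQBwAAFAIAAAAAAADIAAAAAAAAAAEAAAAlAAAAAQAA
ALAEAADcAgAAAAAAAMcAAAAAAAAACgAAAHicY2CAgEpGBgYWRhCrwZ6BwcGBgeGDM0NDngtM7hMT
A0M/A0yeASiv6czAEOsMEgHJZbMwMPSiyFsB5brA8iC5J6wMDM0o8gJAOS2wPEgulh1oIwOS/Q3H
nBkOuIPtB8ldAOJiZHmGIqD7eFwATbwawXicY2SAgEpGBobNYFaDPZBwYGDoc2Zg+O7MCJX7xMTA
sA8u7+DA0DDRmeEAtwtIHiSXzQJRB5FfANRf6cLg4OYKEgLJbQBiVxTzmYHm1zsDAJyZEn3grGgk
AAEAAAIAAAAAAAAAAAAAAAAAAAABAAAAsAQAAOIEAAAAAAAAAAQAAAAAAAABAAIAAAAAAAAAAAAA
AAAA0AcAABsEAAAAAAAAcgAAAAAAAAABAAAAAAAAAAEAAACwBAAAjQQAAAAAAABVAAAAAAAAAAMA
AAB4nGNggIAnrAwMi5lArAZ7BgYHB4YDJS4MC065wOQusDMwJDMiy8u7MCiscgEASvsLiHicY2SA
gA0sDAz6zCBWgz0DwwIHhgNXXBgYelwBNJ0FMOCsaCQAAQAAAgAAAAAAAAAAAAAAAAAAAAEAAACw
BAAArQUAAAAAAAAABAAAAAAAAAEAAgAAAAAAAAAAAAAAAADQBwAAWgUAAAAAAAAyAAAAAAAAAAEA
AAAAAAAAAQAAALAEAACMBQAAAAAAACEAAAAAAAAA6/KJhw==
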