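JvyPiAQAAgCYAAAAAAAAANQAAAAAAAAAbQIAAAAAAAAAAAAAAAAAAAAAAABwAAAAAAAAACwBAAAA
AAAAAAAAABABAAAAAAAA4QIAAAAAAABABAAAAAAAAEAEAAAAAAAAtAQAAAAAAAAyBQAAAAAAAD0E
AAAAAAAAAAAAQC3KIsAAAABAHfwjQAAASivM/Z9AP8ex8wXR40CRjMp4AAEAAAQAAAAIAAAAAgAA
AAAAAAAAAAAAAAAAAAEAAgBjaHIxAAAAANAHAABjaHIyAQAAALAEAAACAAAAAAAAAHicY2CAgNPs
DHDAyCAOphWA+DWfnQOItgHiJz+fO4DoFCCexzvrAIguBOIIm4UOu4D0MyDuYvx6AER/B+KD+iIH
RRgZGFyBODQi0QFMA/GOu+v2g+h0IF6XIOAIoquB+GoNt+MCIL0RiLe0LHHwY2JgKAdirh1bHEB0
IxBLZmQ7aDAzMOgCcde/JQ4gOhqIi5dUHshmYWCoA+LSNCFHEN0JxG9WbnM4zwp0DxDrr7rmsISN
geEkEGcFih0E0e+BeMmbJQcUgf53A+Ifh7MOgOhUIPbf8tlhFjskbE5d77IHAHJmRVR4nGNkgIC1
LAxwwMggCKbZgZjltLDjQiC9C4jPZ7c4vATS3IwMDE9bjBxAND8Qr1ba6WAKpP2B+NUDeUcQnQPE
b3e/OwCiW4D4Y9B+BxC9HohPzbnp8IeJgUGYmYHhcvNCOxCtBMTucv0H9IG0FxDffrzdAUSHAfEW
hlsHQHQTEFsvlHYE0f1AbP9u7gEQvQuI5/OecCgG+qEOiMWDwxxANMhPD6MVHAAwdTCH4KxoJAAB
AAACAAAAAAAAAAAAAAAAAAAAAQAAAK0EAABtAgAAAAAAAAAEAAAAAAAAAQACAAAAAAAAAAAAAAAA
AMsHAADcAAAAAAAAAOUAAAAAAAAAAQAAAAAAAAABAAAArQQAAMEBAAAAAAAArAAAAAAAAAANAAAA
eJxjYIAAAUYGhnVA+qC+yMEnP587LNi48HC00x1XmJwCEwNDBZC94+66/esSBBzPbeN3qWirA8uD
5AyYGRisgeziJZUHuHZscRAw6XXO2XDKBSQPknNgYWDQhsqDcO0u9cPKE5TB8iC5AFYGBjkg+83K
bQ6laUKOIktynFmWfgbLg+QS2BgYNIBs/VXXHEA4VqvN2YzxIVgeJFfAzsDQD2RnBYod9N/y2eFz
993D78LPgt0HkrsAxIZA9qnrXfYgnDsrxOnlnDQnAFIaRtt4nGNkgAABRgYGNyD9tMXIgeW0sONf
7n7n7p8bXRihcgpMDAxVQPbb3e8OvHog78i57r3zu5Y7riB5kJwBMwODOpDtLtd/4Pbj7Q6zwiIO
2a5d7gySB8k5sDAwdAHZWxhuHbBeKO1YKKzvUr33DVg/SG4DEFsB2Q+jFRzEg8McDs6UcuY0v+gM
AKMpKdrgrGgkAAEAAAIAAAAAAAAAAAAAAAAAAAABAAAAsAQAAEAEAAAAAAAAAAQAAAAAAAABAAIA
AAAAAAAAAAAAAAAA0AcAAOUCAAAAAAAAzgAAAAAAAAABAAAAAAAAAAEAAACwBAAAswMAAAAAAACN
AAAAAAAAAAQAAAB4nGNggAAHFgaGHkYGhoP6IgfXJQg4nhPa7nw7MNANJneBnYGBDSifFSh2sDRN
yJGd/5lTtLqSGwCHsA2deJxjZIAABxYGhkJGBoa3u98dePVA3rG1dIPLC74GN0ao3AYgtgKyH0Yr
OIgHhzkcnCnlzGl+0RkA9LcQvOCsaCQAAQAAAgAAAAAAAAAAAAAAAAAAAAEAAACwBAAAMgUAAAAA
AAAABAAAAAAAAAEAAgAAAAAAAAAAAAAAAADQBwAAuAQAAAAAAAA9AAAAAAAAAAEAAAAAAAAAAQAA
ALAEAAD1BAAAAAAAAD0AAAAAAAAAJvyPiA==
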