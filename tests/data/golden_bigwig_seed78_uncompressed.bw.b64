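JvyPiAQAAgCYAAAAAAAAANQAAAAAAAAAdAIAAAAAAAAAAAAAAAAAAAAAAABwAAAAAAAAAAAAAAAA
AAAAAAAAAEAAAAAAAAAA6AIAAAAAAAAsBQAAAAAAAAABAAAAAAAAoAUAAAAAAADEBgAAAAAAALsC
AAAAAAAAAAAAgKSrIMAAAABAM18iQAAAUr0/rXBArZx49XqC00CRjMp4AAEAAAQAAAAIAAAAAgAA
AAAAAAAAAAAAAAAAAAEAAgBjaHIxAAAAANAHAABjaHIyAQAAALAEAAACAAAAAAAAAAAAAAAGAgAA
zgcAAAAAAAAAAAAAAQATAAYCAAAQAgAAPHD+vxACAAA+AgAADPnrQD4CAABDAgAAkHx2wEMCAABd
AgAA+d1lP40DAACXAwAAJjehQJcDAADBAwAABK9awJEFAACTBQAAYaE9PZMFAACmBQAARfA6wKYF
AAC8BQAAUqRqv7wFAADZBQAA2a31QAIHAAATBwAAte2XwBMHAAAmBwAAcuYCQCYHAAAtBwAAzp8R
QS0HAAA+BwAAP1ONQD4HAABfBwAAJrTzQF8HAAB9BwAAzhLfwH0HAACXBwAA4ndrQJcHAAC5BwAA
DmBUvrkHAADOBwAAILoJwAEAAAAAAAAArgQAAAAAAAAAAAAAAQALAAAAAAArAAAAmvkSQVsBAABn
AQAAAB3tQNgBAADcAQAA1meCv9wBAADxAQAAJF0FwRUCAAAdAgAAeVtXPh0CAAA5AgAAqD2qwDQD
AAA4AwAAND63vTgDAABaAwAAQ99kP1oDAACCAwAAyNoKP4IDAACwAwAAO7aNwIIEAACuBAAAxy7Z
wOCsaCQAAQAAAgAAAAAAAAAAAAAABgIAAAEAAACuBAAAdAIAAAAAAAAABAAAAAAAAAEAAgAAAAAA
BgIAAAAAAADOBwAA3AAAAAAAAAD8AAAAAAAAAAEAAAAAAAAAAQAAAK4EAADYAQAAAAAAAJwAAAAA
AAAAEgAAAAAAAAAAAgAAQAIAADoAAACQfHbADPnrQKzQm0MoqSBFAAAAAEACAACAAgAAHQAAAJB8
dsD53WU/Sas8QULsgkIAAAAAgAMAAMADAAAzAAAABK9awCY3oUDFbbPCUyA3RAAAAADAAwAAAAQA
AAEAAAAEr1rABK9awASvWsCKzjpBAAAAAIAFAADABQAALwAAAEXwOsDZrfVAEXAzwpUu0EMAAAAA
wAUAAAAGAAAZAAAA2a31QNmt9UDS7z9D2zK4RAAAAAAABwAAQAcAAD4AAAC17ZfAzp8RQQ9X4EIO
RLpEAAAAAEAHAACABwAAQAAAAM4S38AmtPNACfoXQlUHTkUAAAAAgAcAAMAHAABAAAAAILoJwOJ3
a0AlBnpC7pusQwAAAADABwAA0AcAAA4AAAAgugnAILoJwLgF8cFMq4FCAQAAAAAAAABAAAAAKwAA
AJr5EkGa+RJBZ3/FQ3HGYkUBAAAAQAEAAIABAAAMAAAAAB3tQAAd7UDA1bFCCLckRAEAAADAAQAA
AAIAABkAAAAkXQXB1meCv34dM8Pg5LZEAQAAAAACAABAAgAAJAAAAKg9qsB5W1c+PEcTww01RkQB
AAAAAAMAAEADAAAMAAAAND63vUPfZD9ga9lAxqTNQAEAAABAAwAAgAMAAEAAAADI2go/Q99kP5ps
L0J0sP9BAQAAAIADAADAAwAAMAAAADu2jcDI2go/P6BKwx2uYUQBAAAAgAQAALAEAAAsAAAAxy7Z
wMcu2cApUJXDdlj9ROCsaCQAAQAAAgAAAAAAAAAAAAAAAAIAAAEAAACwBAAALAUAAAAAAAAABAAA
AAAAAAEAAgAAAAAAAAIAAAAAAADQBwAA7AIAAAAAAABAAQAAAAAAAAEAAAAAAAAAAQAAALAEAAAs
BAAAAAAAAAABAAAAAAAACQAAAAAAAAAAAgAAAAMAAFcAAACQfHbADPnrQAa2oUOKwCRFAAAAAAAD
AAAABAAANAAAAASvWsAmN6FAPkO6wo0LOkQAAAAAAAUAAAAGAABIAAAARfA6wNmt9UDNExNDgD7s
RAAAAAAABwAA0AcAAMwAAADOEt/Azp8RQdyKNkMaZaJFAQAAAAAAAAAAAQAAKwAAAJr5EkGa+RJB
Z3/FQ3HGYkUBAAAAAAEAAAACAAAlAAAAJF0FwQAd7UA8ZbTCMqAERQEAAAAAAgAAAAMAACQAAACo
ParAeVtXPjxHE8MNNUZEAQAAAAADAAAABAAAfAAAADu2jcBD32Q/vvkXw+pGa0QBAAAAAAQAALAE
AAAsAAAAxy7ZwMcu2cApUJXDdlj9ROCsaCQAAQAAAgAAAAAAAAAAAAAAAAIAAAEAAACwBAAAxAYA
AAAAAAAABAAAAAAAAAEAAgAAAAAAAAIAAAAAAADQBwAApAUAAAAAAACAAAAAAAAAAAEAAAAAAAAA
AQAAALAEAAAkBgAAAAAAAKAAAAAAAAAAJvyPiA==
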