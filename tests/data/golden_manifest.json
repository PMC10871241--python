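{
 "golden_bigwig_seed77.bw.b64": {
  "kind": "bigwig",
  "seed": 77,
  "chroms": [
   [
    "chr1",
    2000
   ],
   [
    "chr2",
    1200
   ]
  ],
  "interval_count": 40,
  "options": "defaults"
 },
 "golden_bigwig_seed78_uncompressed.bw.b64": {
  "kind": "bigwig",
  "seed": 78,
  "chroms": [
   [
    "chr1",
    2000
   ],
   [
    "chr2",
    1200
   ]
  ],
  "interval_count": 30,
  "options": "compress=False, zoom_levels=[64, 256]"
 },
 "golden_bigbed_seed79.bb.b64": {
  "kind": "bigbed",
  "seed": 79,
  "chroms": [
   [
    "chr1",
    2000
   ],
   [
    "chr2",
    1200
   ]
  ],
  "record_count": 30,
  "bed_n": 6,
  "options": "defaults, bed6 autoSql"
 }
}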