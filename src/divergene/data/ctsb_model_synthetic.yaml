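name: Ctsb-synthetic
chromosome: '14'
strand: +
tss_genomic: 63100000
promoter_bp: 2500
der_bp: 2000
exons:
- - 1
  - 120
- - 1021
  - 1160
- - 2361
  - 2510
- - 3311
  - 3440
- - 4941
  - 5100
- - 5701
  - 5840
- - 6941
  - 7070
- - 7771
  - 7920
- - 9221
  - 9360
- - 10361
  - 10840
cds_mrna:
- 62
- 1471
cds_sequence: null
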