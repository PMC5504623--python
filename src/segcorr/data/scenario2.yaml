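# Synthetic 22-chromosome design for the realistic simulation scenario:
# per-chromosome gene counts, H1 region placements and background
# correlations (rho0 in 0.05-0.28). Generated once from a fixed seed
# and frozen; not derived from any real dataset.
chromosomes:
- name: chr1
  p: 596
  rho0: 0.17
  regions:
  - start: 76
    length: 40
  - start: 188
    length: 40
- name: chr2
  p: 747
  rho0: 0.201
  regions:
  - start: 60
    length: 40
  - start: 136
    length: 20
  - start: 193
    length: 5
  - start: 282
    length: 12
  - start: 331
    length: 6
  - start: 424
    length: 4
- name: chr3
  p: 614
  rho0: 0.198
  regions:
  - start: 96
    length: 30
  - start: 210
    length: 20
  - start: 304
    length: 30
- name: chr4
  p: 248
  rho0: 0.252
  regions:
  - start: 102
    length: 15
  - start: 197
    length: 10
- name: chr5
  p: 429
  rho0: 0.081
  regions:
  - start: 97
    length: 20
  - start: 200
    length: 8
- name: chr6
  p: 493
  rho0: 0.113
  regions:
  - start: 75
    length: 3
  - start: 126
    length: 8
- name: chr7
  p: 470
  rho0: 0.088
  regions:
  - start: 82
    length: 20
  - start: 149
    length: 20
  - start: 231
    length: 3
  - start: 296
    length: 40
  - start: 407
    length: 20
- name: chr8
  p: 707
  rho0: 0.239
  regions:
  - start: 61
    length: 10
  - start: 132
    length: 3
  - start: 166
    length: 4
  - start: 205
    length: 15
  - start: 304
    length: 6
- name: chr9
  p: 244
  rho0: 0.168
  regions:
  - start: 66
    length: 40
  - start: 177
    length: 4
  - start: 220
    length: 5
- name: chr10
  p: 531
  rho0: 0.263
  regions:
  - start: 94
    length: 20
  - start: 202
    length: 10
  - start: 266
    length: 5
- name: chr11
  p: 395
  rho0: 0.164
  regions:
  - start: 66
    length: 5
  - start: 153
    length: 8
  - start: 231
    length: 5
- name: chr12
  p: 255
  rho0: 0.078
  regions:
  - start: 102
    length: 4
  - start: 160
    length: 20
- name: chr13
  p: 654
  rho0: 0.233
  regions:
  - start: 93
    length: 20
  - start: 174
    length: 5
  - start: 253
    length: 10
  - start: 352
    length: 20
  - start: 415
    length: 25
- name: chr14
  p: 586
  rho0: 0.112
  regions:
  - start: 55
    length: 12
  - start: 126
    length: 15
  - start: 196
    length: 12
  - start: 295
    length: 8
  - start: 383
    length: 12
- name: chr15
  p: 581
  rho0: 0.143
  regions:
  - start: 53
    length: 6
  - start: 117
    length: 10
- name: chr16
  p: 572
  rho0: 0.074
  regions:
  - start: 92
    length: 12
  - start: 167
    length: 4
  - start: 242
    length: 4
  - start: 302
    length: 5
  - start: 366
    length: 10
  - start: 443
    length: 40
- name: chr17
  p: 798
  rho0: 0.072
  regions:
  - start: 84
    length: 12
  - start: 144
    length: 4
  - start: 180
    length: 6
- name: chr18
  p: 639
  rho0: 0.094
  regions:
  - start: 54
    length: 5
  - start: 116
    length: 5
  - start: 164
    length: 20
  - start: 262
    length: 20
  - start: 323
    length: 20
  - start: 404
    length: 6
- name: chr19
  p: 423
  rho0: 0.148
  regions:
  - start: 98
    length: 10
  - start: 182
    length: 20
  - start: 254
    length: 25
- name: chr20
  p: 584
  rho0: 0.206
  regions:
  - start: 60
    length: 15
  - start: 117
    length: 6
  - start: 211
    length: 10
- name: chr21
  p: 240
  rho0: 0.19
  regions:
  - start: 90
    length: 15
  - start: 149
    length: 30
- name: chr22
  p: 687
  rho0: 0.239
  regions:
  - start: 97
    length: 4
  - start: 138
    length: 8
  - start: 195
    length: 30
  - start: 295
    length: 8
  - start: 337
    length: 15
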