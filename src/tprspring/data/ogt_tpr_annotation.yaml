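description: Default OGT TPR2-TPR11 annotation built from 34-residue periodicity anchored
  at TPR2 start 55 (R284 at repeat position 26 of TPR8). Approximate boundaries; override
  with exact ones where known.
units:
- id: TPR2
  range:
  - 55
  - 88
  helix_a:
  - 55
  - 66
  helix_b:
  - 71
  - 83
  consensus:
    1: 55
    2: 56
    3: 57
    4: 58
    5: 59
    6: 60
    7: 61
    8: 62
    9: 63
    10: 64
    11: 65
    12: 66
    13: 67
    14: 68
    15: 69
    16: 70
    17: 71
    18: 72
    19: 73
    20: 74
    21: 75
    22: 76
    23: 77
    24: 78
    25: 79
    26: 80
    27: 81
    28: 82
    29: 83
    30: 84
    31: 85
    32: 86
    33: 87
    34: 88
- id: TPR3
  range:
  - 89
  - 122
  helix_a:
  - 89
  - 100
  helix_b:
  - 105
  - 117
  consensus:
    1: 89
    2: 90
    3: 91
    4: 92
    5: 93
    6: 94
    7: 95
    8: 96
    9: 97
    10: 98
    11: 99
    12: 100
    13: 101
    14: 102
    15: 103
    16: 104
    17: 105
    18: 106
    19: 107
    20: 108
    21: 109
    22: 110
    23: 111
    24: 112
    25: 113
    26: 114
    27: 115
    28: 116
    29: 117
    30: 118
    31: 119
    32: 120
    33: 121
    34: 122
- id: TPR4
  range:
  - 123
  - 156
  helix_a:
  - 123
  - 134
  helix_b:
  - 139
  - 151
  consensus:
    1: 123
    2: 124
    3: 125
    4: 126
    5: 127
    6: 128
    7: 129
    8: 130
    9: 131
    10: 132
    11: 133
    12: 134
    13: 135
    14: 136
    15: 137
    16: 138
    17: 139
    18: 140
    19: 141
    20: 142
    21: 143
    22: 144
    23: 145
    24: 146
    25: 147
    26: 148
    27: 149
    28: 150
    29: 151
    30: 152
    31: 153
    32: 154
    33: 155
    34: 156
- id: TPR5
  range:
  - 157
  - 190
  helix_a:
  - 157
  - 168
  helix_b:
  - 173
  - 185
  consensus:
    1: 157
    2: 158
    3: 159
    4: 160
    5: 161
    6: 162
    7: 163
    8: 164
    9: 165
    10: 166
    11: 167
    12: 168
    13: 169
    14: 170
    15: 171
    16: 172
    17: 173
    18: 174
    19: 175
    20: 176
    21: 177
    22: 178
    23: 179
    24: 180
    25: 181
    26: 182
    27: 183
    28: 184
    29: 185
    30: 186
    31: 187
    32: 188
    33: 189
    34: 190
- id: TPR6
  range:
  - 191
  - 224
  helix_a:
  - 191
  - 202
  helix_b:
  - 207
  - 219
  consensus:
    1: 191
    2: 192
    3: 193
    4: 194
    5: 195
    6: 196
    7: 197
    8: 198
    9: 199
    10: 200
    11: 201
    12: 202
    13: 203
    14: 204
    15: 205
    16: 206
    17: 207
    18: 208
    19: 209
    20: 210
    21: 211
    22: 212
    23: 213
    24: 214
    25: 215
    26: 216
    27: 217
    28: 218
    29: 219
    30: 220
    31: 221
    32: 222
    33: 223
    34: 224
- id: TPR7
  range:
  - 225
  - 258
  helix_a:
  - 225
  - 236
  helix_b:
  - 241
  - 253
  consensus:
    1: 225
    2: 226
    3: 227
    4: 228
    5: 229
    6: 230
    7: 231
    8: 232
    9: 233
    10: 234
    11: 235
    12: 236
    13: 237
    14: 238
    15: 239
    16: 240
    17: 241
    18: 242
    19: 243
    20: 244
    21: 245
    22: 246
    23: 247
    24: 248
    25: 249
    26: 250
    27: 251
    28: 252
    29: 253
    30: 254
    31: 255
    32: 256
    33: 257
    34: 258
- id: TPR8
  range:
  - 259
  - 292
  helix_a:
  - 259
  - 270
  helix_b:
  - 275
  - 287
  consensus:
    1: 259
    2: 260
    3: 261
    4: 262
    5: 263
    6: 264
    7: 265
    8: 266
    9: 267
    10: 268
    11: 269
    12: 270
    13: 271
    14: 272
    15: 273
    16: 274
    17: 275
    18: 276
    19: 277
    20: 278
    21: 279
    22: 280
    23: 281
    24: 282
    25: 283
    26: 284
    27: 285
    28: 286
    29: 287
    30: 288
    31: 289
    32: 290
    33: 291
    34: 292
- id: TPR9
  range:
  - 293
  - 326
  helix_a:
  - 293
  - 304
  helix_b:
  - 309
  - 321
  consensus:
    1: 293
    2: 294
    3: 295
    4: 296
    5: 297
    6: 298
    7: 299
    8: 300
    9: 301
    10: 302
    11: 303
    12: 304
    13: 305
    14: 306
    15: 307
    16: 308
    17: 309
    18: 310
    19: 311
    20: 312
    21: 313
    22: 314
    23: 315
    24: 316
    25: 317
    26: 318
    27: 319
    28: 320
    29: 321
    30: 322
    31: 323
    32: 324
    33: 325
    34: 326
- id: TPR10
  range:
  - 327
  - 360
  helix_a:
  - 327
  - 338
  helix_b:
  - 343
  - 355
  consensus:
    1: 327
    2: 328
    3: 329
    4: 330
    5: 331
    6: 332
    7: 333
    8: 334
    9: 335
    10: 336
    11: 337
    12: 338
    13: 339
    14: 340
    15: 341
    16: 342
    17: 343
    18: 344
    19: 345
    20: 346
    21: 347
    22: 348
    23: 349
    24: 350
    25: 351
    26: 352
    27: 353
    28: 354
    29: 355
    30: 356
    31: 357
    32: 358
    33: 359
    34: 360
- id: TPR11
  range:
  - 361
  - 394
  helix_a:
  - 361
  - 372
  helix_b:
  - 377
  - 389
  consensus:
    1: 361
    2: 362
    3: 363
    4: 364
    5: 365
    6: 366
    7: 367
    8: 368
    9: 369
    10: 370
    11: 371
    12: 372
    13: 373
    14: 374
    15: 375
    16: 376
    17: 377
    18: 378
    19: 379
    20: 380
    21: 381
    22: 382
    23: 383
    24: 384
    25: 385
    26: 386
    27: 387
    28: 388
    29: 389
    30: 390
    31: 391
    32: 392
    33: 393
    34: 394
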