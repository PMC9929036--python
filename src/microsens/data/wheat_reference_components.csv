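model,env,sigma2_e,sigma2_P,h2,H2
lmm_het,env01,0.129,0.361,0.150,0.315
lmm_het,env02,0.080,0.311,0.173,0.365
lmm_het,env03,0.038,0.269,0.201,0.423
lmm_het,env04,0.079,0.310,0.174,0.366
lmm_het,env05,0.114,0.346,0.156,0.329
lmm_het,env06,0.068,0.299,0.181,0.380
lmm_het,env07,0.106,0.337,0.160,0.337
lmm_het,env08,0.348,0.579,0.093,0.196
lmm_het,env09,0.054,0.285,0.189,0.399
lmm_het,env10,0.036,0.267,0.202,0.425
lmm_het,env11,0.099,0.330,0.164,0.345
lmm_het,env12,0.072,0.304,0.178,0.374
lmm_het,env13,0.064,0.296,0.183,0.385
lmm_het,env14,0.077,0.308,0.175,0.369
lmm_het,env15,0.067,0.298,0.181,0.381
lmm_het,env16,0.063,0.294,0.183,0.386
lmm_het,env17,0.078,0.309,0.175,0.368
lmm_het,env18,0.064,0.296,0.183,0.385
lmm_het,env19,0.088,0.319,0.169,0.357
lmm_het,env20,0.081,0.312,0.173,0.365
lmm_het,env21,0.046,0.278,0.195,0.410
lmm_het,env22,0.335,0.566,0.095,0.201
lmm_het,env23,0.048,0.280,0.193,0.407
lmm_het,env24,0.090,0.321,0.168,0.354
lmm_het,env25,0.087,0.318,0.170,0.357
lmm_het,env26,0.082,0.313,0.173,0.363
dhglm,env01,0.120,0.344,0.156,0.337
dhglm,env02,0.105,0.329,0.163,0.352
dhglm,env03,0.114,0.338,0.158,0.343
dhglm,env04,0.110,0.334,0.160,0.347
dhglm,env05,0.105,0.329,0.163,0.352
dhglm,env06,0.110,0.335,0.160,0.346
dhglm,env07,0.072,0.297,0.181,0.391
dhglm,env08,0.083,0.307,0.174,0.377
dhglm,env09,0.104,0.329,0.163,0.353
dhglm,env10,0.124,0.348,0.154,0.333
dhglm,env11,0.107,0.331,0.162,0.350
dhglm,env12,0.102,0.327,0.164,0.355
dhglm,env13,0.132,0.356,0.150,0.325
dhglm,env14,0.104,0.328,0.163,0.353
dhglm,env15,0.107,0.331,0.162,0.350
dhglm,env16,0.050,0.274,0.195,0.422
dhglm,env17,0.048,0.272,0.197,0.426
dhglm,env18,0.054,0.278,0.193,0.417
dhglm,env19,0.057,0.281,0.190,0.412
dhglm,env20,0.053,0.277,0.193,0.418
dhglm,env21,0.055,0.279,0.192,0.416
dhglm,env22,0.053,0.277,0.193,0.418
dhglm,env23,0.050,0.274,0.195,0.423
dhglm,env24,0.066,0.290,0.185,0.399
dhglm,env25,0.070,0.294,0.182,0.394
dhglm,env26,0.063,0.287,0.187,0.404
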