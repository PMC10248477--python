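case,Vmax__mri,KE__mri,VD__mri,Vmax__cfd,KE__cfd,VD__cfd
case01,0.49,0.16,0.12,0.51,0.16,0.86
case02,0.43,0.2,0.13,0.38,0.2,0.81
case03,0.3,0.13,0.09,0.27,0.11,0.37
case04,0.45,0.17,0.15,0.48,0.17,0.82
case05,0.35,0.1,0.08,0.24,0.09,0.34
case06,0.48,0.12,0.1,0.31,0.09,0.46
case07,0.71,0.16,0.16,0.35,0.09,0.33
case08,0.46,0.2,0.16,0.45,0.17,0.78
case09,0.58,0.16,0.15,0.3,0.07,0.29
case10,0.58,0.13,0.14,0.31,0.07,0.3
case11,0.63,0.11,0.13,0.26,0.07,0.22
case12,0.52,0.14,0.11,0.33,0.08,0.32
case13,0.49,0.24,0.21,0.32,0.16,0.53
case14,1.01,0.14,0.17,1.23,0.12,1.01
case15,0.55,0.09,0.1,0.43,0.06,0.42
case16,0.82,0.21,0.18,0.42,0.17,0.72
case17,0.46,0.14,0.06,0.47,0.14,0.63
case18,0.82,0.17,0.16,0.34,0.13,0.59
case19,0.36,0.07,0.05,0.42,0.13,0.83
case20,0.73,0.13,0.15,0.36,0.07,0.44
case21,0.56,0.12,0.09,0.26,0.1,0.42
case22,0.9,0.24,0.23,0.48,0.19,1.13
case23,0.62,0.16,0.16,0.31,0.09,0.48
case24,0.73,0.16,0.14,0.44,0.11,0.53
case25,0.8,0.12,0.12,0.32,0.06,0.3
case26,0.66,0.11,0.08,0.4,0.07,0.34
case27,0.67,0.15,0.14,0.4,0.11,0.66
case28,0.76,0.22,0.2,0.43,0.14,0.63
case29,0.86,0.19,0.19,0.87,0.24,1.54
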