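case,Vmean__svc,Vmean__conduit,Vmean__lpa,Vmean__rpa,KE__svc,KE__conduit,KE__lpa,KE__rpa,VD__svc,VD__conduit,VD__lpa,VD__rpa,Diameter__svc,Diameter__conduit,Diameter__lpa,Diameter__rpa
case01,0.16,0.07,0.16,0.25,0.04,0.02,0.03,0.03,0.03,0.01,0.02,0.02,9.29,14.86,7.44,9.12
case02,0.19,0.09,0.14,0.19,0.07,0.03,0.04,0.04,0.04,0.02,0.02,0.03,10.14,14.7,10.49,9.64
case03,0.13,0.07,0.16,0.13,0.02,0.02,0.04,0.02,0.02,0.02,0.03,0.01,10.38,14.81,9.36,9.28
case04,0.15,0.07,0.21,0.19,0.03,0.02,0.05,0.03,0.02,0.02,0.05,0.03,10.33,15.24,9.8,9.06
case05,0.13,0.07,0.17,0.1,0.03,0.02,0.02,0.02,0.02,0.01,0.02,0.01,10.7,13.94,8.32,9.04
case06,0.15,0.07,0.16,0.17,0.03,0.02,0.02,0.02,0.02,0.02,0.02,0.02,7.54,14.69,9.45,7.8
case07,0.11,0.07,0.22,0.16,0.02,0.02,0.08,0.02,0.02,0.02,0.07,0.02,12.49,15.67,9.3,6.74
case08,0.18,0.06,0.21,0.2,0.08,0.01,0.03,0.02,0.05,0.02,0.02,0.02,9.6,12.35,9.92,7.05
case09,0.15,0.09,0.17,0.23,0.03,0.05,0.03,0.04,0.02,0.03,0.03,0.04,10.64,16.6,7.6,7.61
case10,0.16,0.07,0.13,0.19,0.03,0.02,0.02,0.02,0.02,0.04,0.03,0.02,9.87,14.11,8.56,8.73
case11,0.1,0.08,0.14,0.14,0.02,0.03,0.03,0.01,0.02,0.05,0.03,0.01,10.36,15.63,7.87,6.79
case12,0.15,0.08,0.1,0.23,0.05,0.02,0.01,0.03,0.03,0.02,0.01,0.03,9.83,14.54,10.55,8.54
case13,0.16,0.1,0.16,0.24,0.06,0.06,0.04,0.04,0.04,0.07,0.04,0.03,9.81,14.06,11.3,9.96
case14,0.15,0.08,0.23,0.27,0.03,0.03,0.03,0.03,0.02,0.05,0.03,0.04,8.42,15.17,6.54,7.09
case15,0.13,0.06,0.22,0.12,0.02,0.02,0.02,0.0,0.03,0.02,0.03,0.01,10.17,12.63,5.77,7.35
case16,0.17,0.09,0.12,0.26,0.04,0.03,0.01,0.05,0.02,0.03,0.01,0.05,6.95,12.71,6.52,10.94
case17,0.15,0.09,0.22,0.21,0.03,0.02,0.03,0.04,0.01,0.01,0.01,0.01,10.2,12.67,7.89,7.77
case18,0.17,0.09,0.15,0.21,0.06,0.03,0.03,0.02,0.04,0.04,0.03,0.02,10.42,11.82,6.38,7.79
case19,0.15,0.04,0.11,0.21,0.03,0.01,0.01,0.02,0.02,0.0,0.0,0.01,9.83,13.34,8.79,7.39
case20,0.14,0.07,0.2,0.24,0.04,0.02,0.01,0.03,0.04,0.02,0.01,0.04,6.29,12.73,6.71,6.14
case21,0.13,0.09,0.11,0.16,0.03,0.03,0.01,0.02,0.02,0.02,0.01,0.02,10.75,10.72,7.65,9.88
case22,0.16,0.09,0.24,0.31,0.06,0.06,0.05,0.04,0.05,0.04,0.05,0.03,11.68,16.36,7.93,6.46
case23,0.15,0.1,0.13,0.18,0.06,0.05,0.01,0.02,0.04,0.05,0.02,0.03,7.49,13.71,6.27,8.2
case24,0.16,0.09,0.14,0.26,0.06,0.04,0.03,0.02,0.03,0.05,0.02,0.02,9.0,13.76,9.94,8.36
case25,0.12,0.07,0.2,0.15,0.02,0.03,0.04,0.01,0.02,0.04,0.04,0.01,9.87,15.6,8.56,6.84
case26,0.16,0.08,0.12,0.23,0.04,0.02,0.01,0.02,0.02,0.03,0.01,0.01,9.14,11.74,5.91,6.51
case27,0.18,0.08,0.18,0.15,0.05,0.03,0.02,0.02,0.03,0.04,0.02,0.02,8.38,13.06,6.62,10.02
case28,0.2,0.1,0.12,0.2,0.11,0.04,0.02,0.03,0.07,0.08,0.03,0.02,12.02,11.54,6.63,9.35
case29,0.18,0.08,0.17,0.35,0.06,0.02,0.02,0.06,0.04,0.04,0.02,0.06,10.84,14.24,9.07,6.84
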