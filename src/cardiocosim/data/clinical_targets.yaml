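CO: 21.0
Q_UB: 5.6
Q_DAO: 5.7
Q_SH: 9.7
Qp_Qs: 0.9
P_AO: 52.0
P_PUL: 12.0
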