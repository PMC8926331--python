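# 40-target binding panel: serotonin, dopamine, adrenergic receptors,
# monoamine transporters, imidazoline, sigma, opioid, muscarinic and
# histamine receptors, plus the calcium channel and NMDA receptor.
5-HT2A
5-HT2C
5-HT2B
5-HT1A
5-HT1B
5-HT1D
5-HT1E
5-HT5A
5-HT6
5-HT7
D1
D2
D3
D4
D5
Alpha-1A
Alpha-1B
Alpha-2A
Alpha-2B
Alpha-2C
Beta-1
Beta-2
SERT
DAT
NET
I1
Sigma-1
Sigma-2
DOR
KOR
MOR
M1
M2
M3
M4
M5
H1
H2
Ca+
NMDA
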