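label	x	y
Fp1	-0.0718	0.95
Fpz	0.0	0.95
Fp2	0.0718	0.95
AF7	-0.3228	0.7125
AF3	-0.1614	0.7125
AFz	0.0	0.7125
AF4	0.1614	0.7125
AF8	0.3228	0.7125
F7	-0.8096	0.475
F5	-0.6072	0.475
F3	-0.4048	0.475
F1	-0.2024	0.475
Fz	0.0	0.475
F2	0.2024	0.475
F4	0.4048	0.475
F6	0.6072	0.475
F8	0.8096	0.475
FT7	-0.8937	0.2375
FC5	-0.6703	0.2375
FC3	-0.4468	0.2375
FC1	-0.2234	0.2375
FCz	0.0	0.2375
FC2	0.2234	0.2375
FC4	0.4468	0.2375
FC6	0.6703	0.2375
FT8	0.8937	0.2375
T7	-0.92	0.0
C5	-0.69	0.0
C3	-0.46	0.0
C1	-0.23	0.0
Cz	0.0	0.0
C2	0.23	0.0
C4	0.46	0.0
C6	0.69	0.0
T8	0.92	0.0
TP7	-0.8937	-0.2375
CP5	-0.6703	-0.2375
CP3	-0.4468	-0.2375
CP1	-0.2234	-0.2375
CPz	0.0	-0.2375
CP2	0.2234	-0.2375
CP4	0.4468	-0.2375
CP6	0.6703	-0.2375
TP8	0.8937	-0.2375
P7	-0.8096	-0.475
P5	-0.6072	-0.475
P3	-0.4048	-0.475
P1	-0.2024	-0.475
Pz	0.0	-0.475
P2	0.2024	-0.475
P4	0.4048	-0.475
P6	0.6072	-0.475
P8	0.8096	-0.475
PO7	-0.3228	-0.7125
PO3	-0.1614	-0.7125
POz	0.0	-0.7125
PO4	0.1614	-0.7125
PO8	0.3228	-0.7125
O1	-0.0718	-0.95
Oz	0.0	-0.95
O2	0.0718	-0.95
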