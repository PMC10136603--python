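# 62-channel extended 10-20 montage on a 9x9 grid.
# Row 0 = anterior (frontal pole), row 8 = posterior (occipital);
# column 0 = left hemisphere, column 8 = right. 0-based (row, col).
# This is the package's canonical reconstruction of the standard
# 62-channel 9x9 arrangement; it is a convention, overridable by the user.
# NAME	row	col
FP1	0	3
FPZ	0	4
FP2	0	5
AF3	1	3
AF4	1	5
F7	2	0
F5	2	1
F3	2	2
F1	2	3
FZ	2	4
F2	2	5
F4	2	6
F6	2	7
F8	2	8
FT7	3	0
FC5	3	1
FC3	3	2
FC1	3	3
FCZ	3	4
FC2	3	5
FC4	3	6
FC6	3	7
FT8	3	8
T7	4	0
C5	4	1
C3	4	2
C1	4	3
CZ	4	4
C2	4	5
C4	4	6
C6	4	7
T8	4	8
TP7	5	0
CP5	5	1
CP3	5	2
CP1	5	3
CPZ	5	4
CP2	5	5
CP4	5	6
CP6	5	7
TP8	5	8
P7	6	0
P5	6	1
P3	6	2
P1	6	3
PZ	6	4
P2	6	5
P4	6	6
P6	6	7
P8	6	8
PO7	7	1
PO5	7	2
PO3	7	3
POZ	7	4
PO4	7	5
PO6	7	6
PO8	7	7
CB1	8	2
O1	8	3
OZ	8	4
O2	8	5
CB2	8	6
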