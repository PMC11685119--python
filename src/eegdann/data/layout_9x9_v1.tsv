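name	row	col	x	y
FP1	0	3	-0.250	1.000
FPZ	0	4	0.000	1.000
FP2	0	5	0.250	1.000
AF3	1	3	-0.250	0.750
AF4	1	5	0.250	0.750
F7	2	0	-1.000	0.500
F5	2	1	-0.750	0.500
F3	2	2	-0.500	0.500
F1	2	3	-0.250	0.500
FZ	2	4	0.000	0.500
F2	2	5	0.250	0.500
F4	2	6	0.500	0.500
F6	2	7	0.750	0.500
F8	2	8	1.000	0.500
FT7	3	0	-1.000	0.250
FC5	3	1	-0.750	0.250
FC3	3	2	-0.500	0.250
FC1	3	3	-0.250	0.250
FCZ	3	4	0.000	0.250
FC2	3	5	0.250	0.250
FC4	3	6	0.500	0.250
FC6	3	7	0.750	0.250
FT8	3	8	1.000	0.250
T7	4	0	-1.000	0.000
C5	4	1	-0.750	0.000
C3	4	2	-0.500	0.000
C1	4	3	-0.250	0.000
CZ	4	4	0.000	0.000
C2	4	5	0.250	0.000
C4	4	6	0.500	0.000
C6	4	7	0.750	0.000
T8	4	8	1.000	0.000
TP7	5	0	-1.000	-0.250
CP5	5	1	-0.750	-0.250
CP3	5	2	-0.500	-0.250
CP1	5	3	-0.250	-0.250
CPZ	5	4	0.000	-0.250
CP2	5	5	0.250	-0.250
CP4	5	6	0.500	-0.250
CP6	5	7	0.750	-0.250
TP8	5	8	1.000	-0.250
P7	6	0	-1.000	-0.500
P5	6	1	-0.750	-0.500
P3	6	2	-0.500	-0.500
P1	6	3	-0.250	-0.500
PZ	6	4	0.000	-0.500
P2	6	5	0.250	-0.500
P4	6	6	0.500	-0.500
P6	6	7	0.750	-0.500
P8	6	8	1.000	-0.500
PO7	7	1	-0.750	-0.750
PO5	7	2	-0.500	-0.750
PO3	7	3	-0.250	-0.750
POZ	7	4	0.000	-0.750
PO4	7	5	0.250	-0.750
PO6	7	6	0.500	-0.750
PO8	7	7	0.750	-0.750
CB1	8	2	-0.500	-1.000
O1	8	3	-0.250	-1.000
OZ	8	4	0.000	-1.000
O2	8	5	0.250	-1.000
CB2	8	6	0.500	-1.000
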