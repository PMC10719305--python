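gene	beta_component1	beta_component2
NMI	-27.2	0.0
SIX6	0.0	0.0
FOXF2	-12.1	0.0
NCOA4	-13.7	96804.5
FOXP2	12.6	-101775.9
GIPR	-19.0	0.0
ANKMY1	-32.6	0.0
TNFSF9	-14.7	0.0
UCKL1	-45.0	0.0
ST6GAL2	6.2	0.0
CLDN3	-2.1	21941.6
AMOTL1	0.0	0.0
PSMG3	-12.4	-28758.9
DDX46	40.0	0.0
GMPS	-6.8	0.0
FAR2	-21.6	0.0
ZFAT	0.0	0.0
ADCY10	0.0	0.0
MPPED2	-14.7	0.0
OR5M1	-6.0	0.0
GPM6A	-18.6	0.0
GTF2IRD1	-14.5	0.0
PHACTR3	6.3	0.0
PFKP	2.6	0.0
FKBP6	-11.9	0.0
KRTAP13-4	4.7	-15847.1
C14orf39	2.4	-15364.8
SNORD109B	-6.5	0.0
LOC400940	-6.6	70576.5
KCNK10	0.0	0.0
HLA-F	0.0	0.0
LRTM1	-13.4	-50609.5
STK32B	18.4	0.0
AKAP9	7.1	0.0
NPAS2	125.0	0.0
IL1A	13.3	0.0
SEMA4F	-21.3	0.0
AXIN2	24.3	0.0
KRTAP20-1	5.0	0.0
RPL23P8	18.1	0.0
NKX2-3	0.0	-13689.5
KIRREL2	-13.1	0.0
CHI3L1	4.6	0.0
NT5M	18.8	0.0
C1D	-28.8	0.0
NCAN	3.7	151828.5
MECOM	44.5	0.0
EGR2	54.7	0.0
CLEC5A	-10.4	0.0
LUZP6	-73.9	0.0
PDF	-1.4	8045.7
TRPS1	-16.7	0.0
FLJ16779	0.0	-87806.8
KCNQ3	23.4	0.0
CMKLR1	18.1	0.0
SLC25A24	-6.0	-77923.0
CCR5	-20.3	0.0
GABRA4	-6.2	0.0
C1QTNF7	-10.6	0.0
COL4A3	0.0	34903.1
OR5AS1	-39.6	0.0
MTNR1B	11.7	0.0
TFAP2C	7.9	0.0
MMP2	0.0	0.0
NMNAT2	-12.0	0.0
GNG2	7.1	0.0
AKAP12	6.6	0.0
BCKDK	0.0	0.0
OC90	0.8	80377.8
PSD2	5.4	-82538.6
ZFP42	-13.8	0.0
LHFPL2	21.5	0.0
FGFR1	14.0	0.0
CALB1	-5.9	0.0
STAU2	0.0	0.0
KIRREL3	-10.3	0.0
TCHH	-17.8	0.0
OLFM3	10.3	0.0
HECA	-6.8	0.0
MAPT	-14.1	0.0
SLTM	-133.5	0.0
MT1A	0.0	125763.0
SYDE1	4.2	-364254.7
NOC4L	0.0	0.0
NUDT13	-7.3	0.0
RNASE3	7.0	0.0
CNDP2	0.0	0.0
STON1-GTF2A1L	-21.3	0.0
PLCD3	58.7	0.0
NFATC1	-20.3	0.0
LBP	-7.7	0.0
MAP1LC3A	5.8	0.0
SEMA7A	21.4	0.0
MYLK3	21.9	0.0
CROCC	18.2	0.0
SOST	-2.5	0.0
RFPL4B	0.0	0.0
OPCML	21.4	0.0
TLE4	-7.2	0.0
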