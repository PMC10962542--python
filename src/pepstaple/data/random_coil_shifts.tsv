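# Random-coil Calpha and Halpha chemical shifts (ppm) for short unstructured
# peptides/disordered proteins, referenced to DSS.  Approximate literature
# consensus values; intended as a convenience default only — every
# quantitative test in this package uses synthetic tables, and users doing
# quantitative work should load the reference set matching their conditions.
# columns: residue  delta_ca_ppm  delta_ha_ppm
A	52.5	4.32
C	58.2	4.55
D	54.2	4.64
E	56.6	4.35
F	58.0	4.62
G	45.1	3.96
H	55.0	4.73
I	61.3	4.17
K	56.4	4.32
L	55.1	4.34
M	55.3	4.48
N	52.8	4.74
P	63.1	4.42
Q	56.6	4.34
R	56.0	4.34
S	58.3	4.47
T	62.1	4.35
V	62.3	4.12
W	57.7	4.66
Y	58.1	4.55
pS	58.3	4.47
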