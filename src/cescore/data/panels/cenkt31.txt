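# 31 centromere/kinetochore genes: CENP-A, CCAN subcomplexes, KMN network,
# and CENP-A assembly factors (HJURP, MIS18 complex).
CENP-A
CENP-C
CENP-H
CENP-I
CENP-K
CENP-L
CENP-M
CENP-N
CENP-O
CENP-P
CENP-Q
CENP-R
CENP-S
CENP-T
CENP-U
CENP-W
CENP-X
KNL1
MIS12
DSN1
NSL1
PMF1
NDC80
NUF2
SPC24
SPC25
ZWINT
HJURP
MIS18A
MIS18B
M18BP1
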