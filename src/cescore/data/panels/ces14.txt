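# 14-gene core panel: consistently tumour-overexpressed genes with
# prognostic evidence. MIS18B is also known as OIP5; CENP-U as MLF1IP.
CENP-A
CENP-K
CENP-L
CENP-M
CENP-N
CENP-U
CENP-W
HJURP
MIS18B
NDC80
NUF2
SPC24
SPC25
ZWINT
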