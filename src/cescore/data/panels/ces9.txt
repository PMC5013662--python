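# Simplified 9-gene panel: the core panel restricted to genes with probes
# on the Affymetrix HG-U133A platform (drops CENP-W, CENP-L, CENP-K,
# SPC24, NUF2).
CENP-A
CENP-M
CENP-N
CENP-U
HJURP
MIS18B
NDC80
SPC25
ZWINT
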