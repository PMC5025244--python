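# Default driver-gene list: recurrently mutated genes in the tumour type
# under study. Only the two uncontroversial liver-cancer drivers are
# pre-filled; replace/extend with your own curated list (e.g. the most
# frequently mutated genes from a somatic-mutation catalog).
TP53
CTNNB1
# slot: add gene symbol, one per line
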