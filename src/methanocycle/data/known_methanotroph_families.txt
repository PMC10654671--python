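# Families with established aerobic, intra-aerobic, or anaerobic methanotrophy.
# Calls in these families skip the novel-family scaffold verification rule.
Methylomonadaceae
Methylococcaceae
Methylacidiphilaceae
Methylomirabilaceae
Methanoperedenaceae
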