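# Pre-defined selection hierarchy for measure RR.
# One input-route id per line, highest priority first.
# Edit and reinstall (or run from a source checkout) to re-rank.
2x2
props
rr_ci
or_ci
logor_se
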