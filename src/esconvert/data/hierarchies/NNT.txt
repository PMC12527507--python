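# Pre-defined selection hierarchy for measure NNT.
# One input-route id per line, highest priority first.
# Edit and reinstall (or run from a source checkout) to re-rank.
2x2
props
or_ci
logor_se
rr_ci
means_sd
change_scores
ancova_means
means_se
means_ci
md_se
md_ci
t
f
p
eta2
med_iqr_range
med_iqr
med_range
r_n
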