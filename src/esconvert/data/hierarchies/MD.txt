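# Pre-defined selection hierarchy for measure MD.
# One input-route id per line, highest priority first.
# Edit and reinstall (or run from a source checkout) to re-rank.
means_sd
means_se
means_ci
md_se
md_ci
med_iqr_range
med_iqr
med_range
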