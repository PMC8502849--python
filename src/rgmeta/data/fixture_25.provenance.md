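SYNTHETIC dataset. These 25 study records were constructed by rgmeta's
fixture generator; they are NOT the coded samples of any published
P-CAT reliability-generalization study, whose per-study values are not
publicly deposited. The fixture is calibrated so that the pipeline's
output *pattern* matches published headline figures (pooled alpha near
0.81 with a 95% CI near 0.79-0.84, tau^2-based I^2 near 86%, total N
near 15,149, a negative age-reliability correlation, and per-moderator
availability counts of 25/22/22/21/17/5/4 for year, women, men, age
mean, age SD, score mean and score SD). The joint distribution of
sample size, age and reliability across studies is an assumption of the
generator, including one dominant large sample and a long tail of small
ones; it was not extracted from any publication.
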