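"""Parameter-recovery check: can the model find the weights that generated the data?

Simulates experiments at two population settings of (mu_w, sigma_w), refits
each, and reports the bias and RMSE of the posterior-mean hyperparameters and
how often the 95% credible interval covers the truth.  Small grid and few
replications here to keep the example quick; increase both for a real study.
At this cohort size (60 participants) an occasional ConvergenceWarning is
expected — the fit flags it rather than failing silently.
"""

from skewsample import ExperimentDesign, MCMCConfig, recovery_study

table = recovery_study(
    grid=[(0.3, 0.2), (0.7, 0.2)],
    design=ExperimentDesign(n_participants=60, seed=0),
    n_replications=3,
    seed=42,
    config=MCMCConfig(n_chains=2, n_iterations=2500, n_warmup=1000, seed=0),
)
print(table.round(3).to_string(index=False))
print(
    "\nbias near 0 and coverage near 1 mean the hierarchical fit recovers the"
    "\npopulation weight at this design size."
)
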