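"""Bayesian sampling-without-replacement models of visual foraging.

Models foraging as weighted sampling without replacement from the pool of
remaining targets, decomposing selection sequences into interpretable
biases — sticking with the previous target class (p_s), preferring one
class (p_a), and in the spatial variant proximity (sigma_d) and
direction/momentum (sigma_theta) weighting — estimated by MCMC with
optional participant-level random effects.
"""

from .bag import (BagForagingModel, BagParams, class_probability, fit_bag,
                  simulate_bag_trial, trial_loglik)
from .data import (Dataset, RunSummary, Stimulus, Target, TargetClass, Trial,
                   intertarget_distances, read_trials, run_summary,
                   write_trials)
from .harness import (DetectionRule, PowerResult, anova_runstat,
                      differentiation_design, extreme_bias_probe,
                      misattribution_design, run_power_study)
from .inference import (Interval, MCMCSettings, PosteriorDraws, convergence,
                        hpdi, prob_positive)
from .ppc import PpcReport, posterior_predict, ppc_report
from .spatial import (SelectionState, SpatialForagingModel, SpatialParams,
                      angular_deviation, fit_spatial, proximity_weight,
                      selection_distribution, simulate_spatial_trial,
                      spatial_trial_loglik)
from .stimuli import (ExperimentDesign, StimulusSpec, generate_experiment,
                      make_stimulus)

__version__ = "0.1.0"
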