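"""Default study-design configuration for the synthetic cohort.

The defaults emulate the single-patient longitudinal design the analysis was
built for: three pre-treatment (diseased baseline) replicates, four healthy
control samples, and five single-replicate treated time points spanning a
chaperone-therapy phase and a switch to enzyme replacement therapy (ERT).
The latent response level alpha (0 = diseased baseline state, 1 = healthy
control state) follows the observed narrative: minimal change one month in,
a strong response at four months, partial stabilisation at five, relapse by
nine months, and renewed improvement shortly after the ERT switch.
"""

from __future__ import annotations

import copy

import yaml

#: Default cohort configuration. Units: times in months, library sizes in
#: reads, effects in log2 fold change (diseased baseline vs healthy control).
DEFAULT_COHORT: dict = {
    "n_genes": 20000,
    "n_baseline": 3,
    "n_control": 4,
    "n_up": 551,
    "n_down": 347,
    "effect_low": 1.0,
    "effect_high": 4.0,
    "treated_alphas": [
        ["t1", 0.10],
        ["t2", 0.80],
        ["t3", 0.50],
        ["t4", 0.05],
        ["t5", 0.60],
    ],
    # months at which each sample was taken (baseline replicates during the
    # pre-treatment phase; chaperone starts at month 3, ERT at month 12)
    "baseline_times": [0.0, 1.5, 3.0],
    "control_times": [0.0, 0.0, 1.5, 1.5],
    "treated_times": {"t1": 4.0, "t2": 7.0, "t3": 8.0, "t4": 12.0, "t5": 12.5},
    "phase_of_treated": {
        "t1": "chaperone",
        "t2": "chaperone",
        "t3": "chaperone",
        "t4": "chaperone",
        "t5": "ERT",
    },
    "library_size_mean": 5_000_000.0,
    "library_size_sdlog": 0.2,  # ~ +/-20% lognormal spread
    "dispersion": 0.1,  # NB: var = mu + dispersion * mu^2
    "mean_log": 4.0,  # lognormal(meanlog, sdlog) for control-state means
    "sd_log": 1.2,
    "interp_space": "log2",  # or "linear"
    "noise": "nb",  # "nb" | "none" (deterministic rounded means)
    "seed": 0,
}

#: Default clinical scenario: eGFR falls from 42 to 30 ml/min/1.73m^2 over 13
#: months, declining fastest pre-treatment, slowest on chaperone therapy, and
#: faster again after the ERT switch.
DEFAULT_CLINICAL: dict = {
    "start_value": 42.0,
    "phase_slopes": {"pre": -2.0, "chaperone": -0.5, "ERT": -1.5},
    "phase_breaks": [3.0, 12.0],
    "t_start": 0.0,
    "t_end": 13.0,
    "dt": 1.0,
    "noise_sd": 0.5,
}


def default_cohort_config() -> dict:
    return copy.deepcopy(DEFAULT_COHORT)


def default_clinical_config() -> dict:
    return copy.deepcopy(DEFAULT_CLINICAL)


def load_config(path) -> dict:
    """Load a YAML cohort config, filling unspecified keys from the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_cohort_config()
    cfg.update(user)
    return cfg
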