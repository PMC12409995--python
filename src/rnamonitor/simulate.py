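"""Synthetic longitudinal cohort generator.

Simulates the statistical structure the monitoring analysis assumes: a
gene x sample negative-binomial count matrix for a diseased baseline
(pre-treatment replicates), healthy controls, and single-replicate treated
time points whose expected expression interpolates between the diseased and
healthy states according to a latent response level alpha in [0, 1]
(0 = diseased baseline, 1 = healthy control). A piecewise-linear clinical
series (eGFR, uPCR) with per-phase slopes accompanies the expression data.

Ground truth (planted per-gene log2 fold changes and per-sample alphas) is
returned alongside the counts so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config as _config
from .containers import CountMatrix

__all__ = [
    "CohortDesign",
    "SyntheticTruth",
    "sample_signature",
    "simulate_counts",
    "simulate_clinical_series",
    "simulate_cohort",
]


@dataclass
class CohortDesign:
    """Study design for a simulated cohort.

    ``treated_alphas`` is an ordered list of (time_label, alpha) pairs, one
    per single-replicate treated sample. NB dispersion follows the
    var = mu + dispersion * mu^2 convention; ``dispersion == 0`` degenerates
    to Poisson counts, and ``noise="none"`` replaces sampling with rounded
    expected counts (useful for noiseless trajectory checks).
    """

    n_genes: int
    n_baseline: int = 3
    n_control: int = 4
    treated_alphas: list[tuple[str, float]] = field(default_factory=list)
    library_size_mean: float = 5_000_000.0
    library_size_sdlog: float = 0.2
    dispersion: float = 0.1
    mean_log: float = 4.0
    sd_log: float = 1.2
    interp_space: str = "log2"
    noise: str = "nb"
    seed: int = 0
    baseline_times: list[float] | None = None
    control_times: list[float] | None = None
    treated_times: dict[str, float] | None = None
    phase_of_treated: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_baseline < 2 or self.n_control < 2:
            raise ValueError("need >=2 baseline and >=2 control samples for group means")
        labels = [lbl for lbl, _ in self.treated_alphas]
        if len(set(labels)) != len(labels):
            raise ValueError("treated time labels must be unique")
        for lbl, a in self.treated_alphas:
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"alpha for {lbl!r} outside [0, 1]: {a}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        if self.interp_space not in ("log2", "linear"):
            raise ValueError("interp_space must be 'log2' or 'linear'")
        if self.noise not in ("nb", "none"):
            raise ValueError("noise must be 'nb' or 'none'")

    @classmethod
    def from_config(cls, cfg: dict) -> "CohortDesign":
        return cls(
            n_genes=int(cfg["n_genes"]),
            n_baseline=int(cfg["n_baseline"]),
            n_control=int(cfg["n_control"]),
            treated_alphas=[(str(l), float(a)) for l, a in cfg["treated_alphas"]],
            library_size_mean=float(cfg["library_size_mean"]),
            library_size_sdlog=float(cfg["library_size_sdlog"]),
            dispersion=float(cfg["dispersion"]),
            mean_log=float(cfg["mean_log"]),
            sd_log=float(cfg["sd_log"]),
            interp_space=str(cfg["interp_space"]),
            noise=str(cfg["noise"]),
            seed=int(cfg["seed"]),
            baseline_times=list(cfg.get("baseline_times") or []) or None,
            control_times=list(cfg.get("control_times") or []) or None,
            treated_times=dict(cfg.get("treated_times") or {}) or None,
            phase_of_treated=dict(cfg.get("phase_of_treated") or {}) or None,
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-gene effects, per-sample alphas, state means.

    ``alphas`` covers every sample (baseline samples at 0, controls at 1 by
    convention); ``control_state_means`` are the expected healthy-state counts
    per gene at the reference library size.
    """

    signature: pd.DataFrame  # gene_id, true_log2fc, direction
    alphas: dict[str, float]
    control_state_means: pd.Series

    def signature_genes(self, direction: str | None = None) -> list[str]:
        sig = self.signature
        if direction is None:
            sel = sig["direction"] != "null"
        else:
            sel = sig["direction"] == direction
        return sig.loc[sel, "gene_id"].tolist()


def sample_signature(
    n_genes: int,
    n_up: int = 551,
    n_down: int = 347,
    effect_low: float = 1.0,
    effect_high: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a planted disease signature over a gene universe.

    Exactly ``n_up`` genes get log2 fold changes uniform on
    [effect_low, effect_high], ``n_down`` on [-effect_high, -effect_low]
    (diseased baseline relative to healthy control); the remainder are null.
    Deterministic for a given seed.
    """
    if n_up + n_down > n_genes:
        raise ValueError(
            f"signature larger than gene universe: n_up + n_down = {n_up + n_down} "
            f"> n_genes = {n_genes}"
        )
    if not 0 < effect_low <= effect_high:
        raise ValueError("need 0 < effect_low <= effect_high")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    gene_ids = [f"gene_{i:0{width}d}" for i in range(1, n_genes + 1)]
    perm = rng.permutation(n_genes)
    lfc = np.zeros(n_genes)
    lfc[perm[:n_up]] = rng.uniform(effect_low, effect_high, size=n_up)
    lfc[perm[n_up : n_up + n_down]] = -rng.uniform(effect_low, effect_high, size=n_down)
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "null"))
    return pd.DataFrame(
        {"gene_id": gene_ids, "true_log2fc": lfc, "direction": direction}
    )


def _expected_means(
    design: CohortDesign, control_means: np.ndarray, lfc: np.ndarray, alpha: float
) -> np.ndarray:
    """Expected counts for a sample at response level alpha (library scale 1)."""
    if design.interp_space == "log2":
        return control_means * 2.0 ** ((1.0 - alpha) * lfc)
    baseline_means = control_means * 2.0**lfc
    return alpha * control_means + (1.0 - alpha) * baseline_means


def simulate_counts(
    design: CohortDesign, signature: pd.DataFrame
) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate the cohort count matrix and its ground truth.

    Healthy-state per-gene means are lognormal draws rescaled so a control
    sample's expected library size equals ``library_size_mean``; treated
    means interpolate toward the diseased state in log2 space (linear-CPM
    interpolation behind ``interp_space="linear"``). Counts are NB with the
    given dispersion, scaled by sample-specific lognormal library factors.
    """
    if len(signature) != design.n_genes:
        raise ValueError(
            f"signature covers {len(signature)} genes but design has {design.n_genes}"
        )
    rng = np.random.default_rng(design.seed)
    gene_ids = signature["gene_id"].to_numpy()
    lfc = signature["true_log2fc"].to_numpy(dtype=float)

    raw = rng.lognormal(design.mean_log, design.sd_log, size=design.n_genes)
    control_means = raw * design.library_size_mean / raw.sum()
    if not np.isfinite(control_means).all():
        raise ValueError("non-finite control-state means")

    samples: list[tuple[str, str, float, str, float]] = []  # id, group, alpha, phase, time
    bt = design.baseline_times or [float(i) for i in range(design.n_baseline)]
    ct = design.control_times or [0.0] * design.n_control
    for i in range(design.n_baseline):
        t = bt[i] if i < len(bt) else float(i)
        samples.append((f"baseline_{i + 1}", "baseline", 0.0, "pre", t))
    for i in range(design.n_control):
        t = ct[i] if i < len(ct) else 0.0
        samples.append((f"control_{i + 1}", "control", 1.0, "pre", t))
    tt = design.treated_times or {}
    ph = design.phase_of_treated or {}
    for j, (label, alpha) in enumerate(design.treated_alphas):
        samples.append(
            (label, "treated", float(alpha), ph.get(label, "chaperone"), tt.get(label, float(j)))
        )

    n_samples = len(samples)
    lib_factors = (
        rng.lognormal(0.0, design.library_size_sdlog, size=n_samples)
        if design.library_size_sdlog > 0
        else np.ones(n_samples)
    )

    counts = np.empty((design.n_genes, n_samples), dtype=np.int64)
    for j, (sid, group, alpha, phase, t) in enumerate(samples):
        mu = _expected_means(design, control_means, lfc, alpha) * lib_factors[j]
        if design.noise == "none":
            counts[:, j] = np.rint(mu).astype(np.int64)
        elif design.dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            n_nb = 1.0 / design.dispersion
            p_nb = n_nb / (n_nb + mu)
            counts[:, j] = rng.negative_binomial(n_nb, p_nb)

    sample_ids = [s[0] for s in samples]
    meta = pd.DataFrame(
        {
            "group": [s[1] for s in samples],
            "time_months": [s[4] for s in samples],
            "phase": [s[3] for s in samples],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids), meta)
    truth = SyntheticTruth(
        signature=signature,
        alphas={s[0]: s[2] for s in samples},
        control_state_means=pd.Series(control_means, index=gene_ids),
    )
    return cm, truth


def simulate_clinical_series(
    phase_slopes: dict[str, float],
    phase_breaks: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    start_value: float = 42.0,
    t_start: float = 0.0,
    t_end: float = 13.0,
    dt: float = 1.0,
    marker: str = "egfr",
) -> pd.DataFrame:
    """Simulate a piecewise-linear clinical marker series with Gaussian noise.

    Phases are contiguous: phase i covers [break_{i-1}, break_i) with the
    final phase closed on the right. The mean is continuous across breaks.
    Returns a DataFrame with columns time_months, <marker>, phase.
    """
    phases = list(phase_slopes)
    if len(phase_breaks) != len(phases) - 1:
        raise ValueError("need exactly one break fewer than phases")
    if any(not np.isfinite(s) for s in phase_slopes.values()):
        raise ValueError("slopes must be finite")
    breaks = [t_start, *phase_breaks, t_end]
    if any(b1 >= b2 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("phase windows must be increasing and non-overlapping")

    rng = np.random.default_rng(seed)
    times = np.arange(t_start, t_end + dt / 2, dt)
    values = np.empty_like(times)
    labels = []
    # continuous piecewise-linear mean: track the value at each break
    level_at = {t_start: start_value}
    for i, ph in enumerate(phases):
        level_at[breaks[i + 1]] = level_at[breaks[i]] + phase_slopes[ph] * (
            breaks[i + 1] - breaks[i]
        )
    for k, t in enumerate(times):
        i = max(j for j in range(len(phases)) if breaks[j] <= t or j == 0)
        if t >= breaks[-1]:
            i = len(phases) - 1
        values[k] = level_at[breaks[i]] + phase_slopes[phases[i]] * (t - breaks[i])
        labels.append(phases[i])
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    return pd.DataFrame({"time_months": times, marker: values, "phase": labels})


def simulate_cohort(cfg: dict | None = None, seed: int | None = None):
    """Convenience wrapper: signature + counts + truth from a config dict."""
    cfg = dict(cfg or _config.default_cohort_config())
    if seed is not None:
        cfg["seed"] = seed
    design = CohortDesign.from_config(cfg)
    signature = sample_signature(
        n_genes=design.n_genes,
        n_up=int(cfg.get("n_up", 551)),
        n_down=int(cfg.get("n_down", 347)),
        effect_low=float(cfg.get("effect_low", 1.0)),
        effect_high=float(cfg.get("effect_high", 4.0)),
        seed=design.seed,
    )
    cm, truth = simulate_counts(design, signature)
    return cm, truth
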