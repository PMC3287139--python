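"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-channel miRNA array study of metastatic gastric
cancer: ~1,667 mature miRNAs each measured by 4 replicate probes, 90 cancer
and 34 normal biopsy samples for the diagnostic signature, an 82-patient
training cohort with right-censored time to progression (median ~3.1 months
under cisplatin/fluorouracil), and 8 pre/post-treatment sample pairs from
clinical responders.

Three data-generating processes are planted so that every downstream stage
has a recoverable truth:

* differential features — a +/- ``diff_log2_effect`` shift of cancer samples
  (half of the planted features up, half down);
* hazard features — a proportional-hazards latent risk ``r = sum(beta_j x_j)``
  with event times Exponential(rate ``baseline_hazard * exp(r)``) and
  independent Exponential censoring;
* pre/post pairs — pre-treatment samples drawn from the low-risk half of the
  latent score, post-treatment samples shifted by ``pair_shift`` along the
  (unit-normalized) fitted resistance direction.

Replicate probes add technical noise with SD ``noise_sd / 2``: replicates
must be more alike than biological samples for median collapsing to matter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import collapse_replicates

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "generate_cancer_normal",
    "generate_survival_cohort",
    "generate_pairs",
    "generate_ct_table",
]

# Default calibration targets: 3.1-month median observed TTP with a 20%
# censoring fraction (the training cohort this generator emulates).
_TTP_MEDIAN_MONTHS = 3.1
_CENSOR_FRAC = 0.2
_TOTAL_RATE = math.log(2.0) / _TTP_MEDIAN_MONTHS


def _risk_sd(config: "SimulationConfig") -> float:
    """SD of the latent risk r = sum(beta_j x_j) under the planted block."""
    k = config.n_hazard_features
    if k == 0:
        return 0.0
    rho = config.hazard_factor_corr
    h = abs(config.hazard_log_effect)
    # sign-aligned shared factor: r = h*sd*(k*sqrt(rho)*g + sqrt(1-rho)*sum eps)
    return h * config.noise_sd * math.sqrt(rho * k * k + (1.0 - rho) * k)


def _calibrate_rates(sigma_r, median=_TTP_MEDIAN_MONTHS, censor_frac=_CENSOR_FRAC):
    """Event/censor rates giving the target observed-TTP median and censoring
    fraction when individual hazards are lambda0 * exp(r), r ~ N(0, sigma_r^2).

    The observed TTP is min(T, C) with C ~ Exp(lambda_c) independent of r, so
    P(min > m) = exp(-lambda_c m) * E[exp(-lambda0 e^r m)] factorizes and the
    two conditions reduce to a one-dimensional root find in lambda0.
    """
    if sigma_r == 0.0:
        total = math.log(2.0) / median
        return (1.0 - censor_frac) * total, censor_frac * total
    from scipy import optimize
    nodes, weights = np.polynomial.hermite_e.hermegauss(81)
    w = weights / weights.sum()
    er = np.exp(sigma_r * nodes)

    def lam_c(l0):
        surv = float(w @ np.exp(-l0 * er * median))
        if surv <= 0.5:
            return 0.0
        return math.log(surv / 0.5) / median

    def censor_resid(l0):
        lc = lam_c(l0)
        return float(w @ (lc / (lc + l0 * er))) - censor_frac

    # bracket: tiny l0 -> censoring dominates; l0_max has lam_c = 0
    l0_max = optimize.brentq(
        lambda l0: float(w @ np.exp(-l0 * er * median)) - 0.5, 1e-8, 1e3)
    l0 = optimize.brentq(censor_resid, 1e-8, l0_max)
    return l0, lam_c(l0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped simulation parameters; the seed fully determines output."""

    n_cancer: int = 90
    n_normal: int = 34
    n_features: int = 1667
    n_replicates_per_feature: int = 4
    n_diff_features: int = 125         # differential-table-sized signature
    diff_log2_effect: float = 1.0      # log2-units shift of cancer samples
    n_hazard_features: int = 58        # TTP-associated signature size
    hazard_log_effect: float = 0.06    # log hazard per log2-unit of expression
    hazard_factor_corr: float = 0.5    # co-expression of the hazard signature
    # None = calibrate so the observed TTP median is 3.1 months with 20%
    # censoring, accounting for the planted risk spread (events/month)
    baseline_hazard: float | None = None
    censor_rate: float | None = None
    n_pairs: int = 8
    pair_shift: float = 2.0            # magnitude of the post-treatment shift
    noise_sd: float = 0.5              # biological SD, log2 units
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_cancer": self.n_cancer, "n_normal": self.n_normal,
            "n_features": self.n_features,
            "n_replicates_per_feature": self.n_replicates_per_feature,
            "n_diff_features": self.n_diff_features,
            "n_hazard_features": self.n_hazard_features,
            "n_pairs": self.n_pairs,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_diff_features > self.n_features:
            raise ValueError("n_diff_features exceeds n_features")
        if self.n_hazard_features > self.n_features:
            raise ValueError("n_hazard_features exceeds n_features")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.hazard_factor_corr < 1.0:
            raise ValueError("hazard_factor_corr must be in [0, 1)")
        if self.censor_rate is not None and self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")

    def resolved_rates(self) -> tuple:
        """(baseline_hazard, censor_rate), calibrating unset fields to the
        3.1-month median / 20%-censoring study targets."""
        if self.baseline_hazard is not None and self.censor_rate is not None:
            return self.baseline_hazard, self.censor_rate
        l0, lc = _calibrate_rates(_risk_sd(self))
        if self.baseline_hazard is not None:
            l0 = self.baseline_hazard
        if self.censor_rate is not None:
            lc = self.censor_rate
        return l0, lc

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class SyntheticCohort:
    """Probe-level expression plus clinical truth for one simulated study."""

    config: SimulationConfig
    expression: pd.DataFrame            # probes x samples, log2 ratios
    probe_map: pd.Series                # probe id -> miRNA id
    class_labels: pd.Series             # sample id -> cancer/normal
    survival: pd.DataFrame              # sample_id index; ttp_months, event
    truth: pd.DataFrame                 # feature_id, role, effect
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)  # pair_id, pre, post

    def mirna_expression(self) -> pd.DataFrame:
        """Replicate-collapsed (median) feature-by-sample matrix."""
        return collapse_replicates(self.expression, self.probe_map)

    def clinical_table(self) -> pd.DataFrame:
        """Clinical TSV payload: class label, TTP, event, pair id, timepoint."""
        df = pd.DataFrame(index=self.class_labels.index)
        df.index.name = "sample_id"
        df["class_label"] = self.class_labels
        df["ttp_months"] = np.nan
        df["event"] = np.nan
        if len(self.survival):
            df.loc[self.survival.index, "ttp_months"] = self.survival["ttp_months"]
            df.loc[self.survival.index, "event"] = self.survival["event"].astype(float)
        df["pair_id"] = ""
        df["timepoint"] = ""
        for _, row in self.pairs.iterrows():
            df.loc[row["pre"], ["pair_id", "timepoint"]] = [row["pair_id"], "pre"]
            df.loc[row["post"], ["pair_id", "timepoint"]] = [row["pair_id"], "post"]
        return df


def _feature_ids(n):
    width = max(4, len(str(n)))
    return [f"syn-miR-{i + 1:0{width}d}" for i in range(n)]


def _probe_expand(features: pd.DataFrame, n_rep, tech_sd, rng):
    """Replicate each feature row ``n_rep`` times with technical noise."""
    feats = features.index
    probe_ids = [f"{f}_p{r + 1}" for f in feats for r in range(n_rep)]
    base = np.repeat(features.to_numpy(), n_rep, axis=0)
    if tech_sd > 0:
        base = base + rng.normal(0.0, tech_sd, size=base.shape)
    probes = pd.DataFrame(base, index=pd.Index(probe_ids, name="probe_id"),
                          columns=features.columns)
    probe_map = pd.Series(np.repeat(feats.to_numpy(), n_rep), index=probes.index)
    return probes, probe_map


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_cancer_normal(config: SimulationConfig) -> SyntheticCohort:
    """Cancer-vs-normal cohort with planted differential features.

    Feature values are Normal(0, noise_sd^2) per sample on the log2 scale;
    for the ``n_diff_features`` planted features, cancer samples are shifted
    by +/- ``diff_log2_effect`` (half up, half down).
    """
    rng = _rng(config, 0)
    feats = _feature_ids(config.n_features)
    samples = [f"C{i + 1:03d}" for i in range(config.n_cancer)] + \
              [f"N{i + 1:03d}" for i in range(config.n_normal)]
    vals = rng.normal(0.0, config.noise_sd,
                      size=(config.n_features, len(samples)))
    diff_idx = rng.choice(config.n_features, size=config.n_diff_features, replace=False)
    signs = np.where(np.arange(config.n_diff_features) % 2 == 0, 1.0, -1.0)
    vals[diff_idx, :config.n_cancer] += (signs * config.diff_log2_effect)[:, None]
    features = pd.DataFrame(vals, index=pd.Index(feats, name="feature_id"), columns=samples)
    probes, probe_map = _probe_expand(features, config.n_replicates_per_feature,
                                      config.noise_sd / 2.0, rng)
    labels = pd.Series(["cancer"] * config.n_cancer + ["normal"] * config.n_normal,
                       index=samples, name="class_label")
    truth = pd.DataFrame({
        "feature_id": [feats[i] for i in diff_idx],
        "role": "diff",
        "effect": signs * config.diff_log2_effect,
    })
    return SyntheticCohort(config=config, expression=probes, probe_map=probe_map,
                           class_labels=labels,
                           survival=pd.DataFrame(columns=["ttp_months", "event"]),
                           truth=truth)


def _plant_hazard_block(vals, hz_idx, signs, config, rng):
    """Overwrite the planted rows with a sign-aligned latent-factor block.

    Co-regulated signature miRNAs (e.g. polycistronic clusters) rise and
    fall together; each planted feature is
    ``noise_sd * (s_j*sqrt(rho)*g + sqrt(1-rho)*eps_j)`` with a shared
    per-sample activity ``g`` so that marginals stay Normal(0, noise_sd^2)
    while the signature block carries correlation ``rho`` — the data model
    supervised principal components is built for.
    """
    rho = config.hazard_factor_corr
    if len(hz_idx) == 0 or rho == 0.0:
        return
    n_samples = vals.shape[1]
    g = rng.standard_normal(n_samples)
    eps = rng.standard_normal((len(hz_idx), n_samples))
    vals[hz_idx] = config.noise_sd * (
        signs[:, None] * math.sqrt(rho) * g + math.sqrt(1.0 - rho) * eps
    )


def generate_survival_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Training cohort of ``n_cancer`` patients with right-censored TTP.

    The latent risk score is ``r = sum(beta_j x_j)`` over the planted hazard
    features with alternating-sign coefficients ``+/- hazard_log_effect``;
    event times are Exponential(rate baseline_hazard * exp(r)), censoring is
    independent Exponential(censor_rate), TTP = min of the two (months).
    The planted features share a latent activity factor (correlation
    ``hazard_factor_corr``, aligned with each feature's effect sign).
    """
    baseline_hazard, censor_rate = config.resolved_rates()
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    rng = _rng(config, 1)
    feats = _feature_ids(config.n_features)
    samples = [f"S{i + 1:03d}" for i in range(config.n_cancer)]
    vals = rng.normal(0.0, config.noise_sd, size=(config.n_features, len(samples)))
    hz_idx = rng.choice(config.n_features, size=config.n_hazard_features, replace=False)
    signs = np.where(np.arange(config.n_hazard_features) % 2 == 0, 1.0, -1.0)
    betas = signs * config.hazard_log_effect
    _plant_hazard_block(vals, hz_idx, signs, config, rng)
    risk = betas @ vals[hz_idx] if config.n_hazard_features else np.zeros(len(samples))
    rate = baseline_hazard * np.exp(risk)
    event_t = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        censor_t = rng.exponential(1.0 / censor_rate, size=len(samples))
    else:
        censor_t = np.full(len(samples), np.inf)
    ttp = np.minimum(event_t, censor_t)
    event = event_t <= censor_t
    if not event.any():
        warnings.warn("all samples censored: censor_rate dominates the hazard")
    features = pd.DataFrame(vals, index=pd.Index(feats, name="feature_id"), columns=samples)
    probes, probe_map = _probe_expand(features, config.n_replicates_per_feature,
                                      config.noise_sd / 2.0, rng)
    labels = pd.Series("cancer", index=samples, name="class_label")
    survival = pd.DataFrame({"ttp_months": ttp, "event": event.astype(int)},
                            index=pd.Index(samples, name="sample_id"))
    truth = pd.DataFrame({
        "feature_id": [feats[i] for i in hz_idx],
        "role": "hazard",
        "effect": betas,
    })
    return SyntheticCohort(config=config, expression=probes, probe_map=probe_map,
                           class_labels=labels, survival=survival, truth=truth)


def generate_pairs(cohort: SyntheticCohort, model_direction: pd.Series,
                   pair_shift=None, technical_sd=None, seed=None) -> SyntheticCohort:
    """Pre/post-treatment pairs shifted along a fitted resistance direction.

    Pre-treatment feature vectors are rejection-sampled from the base
    distribution conditioned on the planted latent risk falling below its
    median (pairs come from clinical responders, i.e. initially low-risk
    tumors); the post-treatment sample is the same tumor moved ``pair_shift``
    log2-units along the unit-normalized ``model_direction``.  Fresh
    technical noise (default ``noise_sd / 2``) is applied per replicate probe.
    """
    config = cohort.config
    if pair_shift is None:
        pair_shift = config.pair_shift
    if technical_sd is None:
        technical_sd = config.noise_sd / 2.0
    if seed is None:
        rng = _rng(config, 2)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    feats = pd.Index(_feature_ids(config.n_features), name="feature_id")
    direction = pd.Series(model_direction).reindex(feats).fillna(0.0)
    norm = float(np.linalg.norm(direction.to_numpy()))
    if norm == 0:
        raise ValueError("model_direction is zero on the cohort's features")
    unit = direction.to_numpy() / norm

    hz = cohort.truth[cohort.truth["role"] == "hazard"]
    beta = pd.Series(0.0, index=feats)
    beta.loc[hz["feature_id"].to_numpy()] = hz["effect"].to_numpy()
    beta = beta.to_numpy()
    hz_pos = feats.get_indexer(hz["feature_id"].to_numpy())
    signs = np.sign(hz["effect"].to_numpy())
    rho = config.hazard_factor_corr

    def draw_sample():
        x = rng.normal(0.0, config.noise_sd, size=config.n_features)
        if hz_pos.size and rho > 0:
            g = rng.standard_normal()
            eps = rng.standard_normal(hz_pos.size)
            x[hz_pos] = config.noise_sd * (signs * math.sqrt(rho) * g +
                                           math.sqrt(1.0 - rho) * eps)
        return x

    cols, pre_ids, post_ids, pair_ids = [], [], [], []
    for p in range(config.n_pairs):
        for _ in range(10_000):
            x = draw_sample()
            if beta @ x < 0.0:  # below the median (zero) of the latent score
                break
        else:
            raise RuntimeError("rejection sampling of low-risk pre samples failed")
        cols.append(x)
        cols.append(x + pair_shift * unit)
        pair_ids.append(f"P{p + 1}")
        pre_ids.append(f"P{p + 1}_pre")
        post_ids.append(f"P{p + 1}_post")
    sample_ids = [s for pre, post in zip(pre_ids, post_ids) for s in (pre, post)]
    features = pd.DataFrame(np.column_stack(cols), index=feats, columns=sample_ids)
    probes, probe_map = _probe_expand(features, config.n_replicates_per_feature,
                                      technical_sd, rng)
    labels = pd.Series("cancer", index=sample_ids, name="class_label")
    pairs = pd.DataFrame({"pair_id": pair_ids, "pre": pre_ids, "post": post_ids})
    return SyntheticCohort(config=config, expression=probes, probe_map=probe_map,
                           class_labels=labels,
                           survival=pd.DataFrame(columns=["ttp_months", "event"]),
                           truth=cohort.truth, pairs=pairs)


def generate_ct_table(seed=0, n_cancer=4, n_normal=4,
                      targets=None, reference="RNU6",
                      base_ct=25.0, reference_ct=20.0, well_sd=0.3,
                      n_wells=2) -> pd.DataFrame:
    """Synthetic qPCR Ct table in the duplicate-well TSV layout.

    ``targets`` maps miRNA name -> log2 shift of cancer relative to normal
    (one cycle of Ct corresponds to one log2 unit; lower Ct = more abundant).
    Defaults mirror a four-assay validation: two miRNAs up and two down in
    cancer by one cycle.
    """
    if targets is None:
        targets = {"syn-miR-up1": 1.0, "syn-miR-up2": 1.0,
                   "syn-miR-dn1": -1.0, "syn-miR-dn2": -1.0}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    rows = []
    samples = [("QC%d" % (i + 1), "cancer") for i in range(n_cancer)] + \
              [("QN%d" % (i + 1), "normal") for i in range(n_normal)]
    for sample_id, group in samples:
        for w in range(n_wells):
            rows.append({"sample_id": sample_id, "group": group,
                         "well": f"w{w + 1}", "target": reference,
                         "ct": reference_ct + rng.normal(0.0, well_sd)})
        for target, shift in targets.items():
            offset = -shift if group == "cancer" else 0.0
            for w in range(n_wells):
                rows.append({"sample_id": sample_id, "group": group,
                             "well": f"w{w + 1}", "target": target,
                             "ct": base_ct + offset + rng.normal(0.0, well_sd)})
    return pd.DataFrame(rows)
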