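"""Synthetic cohorts with planted edge-behavior signal.

The real study population is a family-structured cohort of healthy young
adults with questionnaire-based personality totals (integer 0-48), simple
covariates, and Fisher-z partial-correlation connectomes.  None of that is
redistributable, so this module generates a stand-in world with the same
shape:

* a cohort table: subjects grouped into families, integer behavior scores
  drawn Gaussian then rounded and clipped to [0, 48], plus age, binary
  gender, intelligence (0-24 count correct) and a head-motion scalar;
* an n x E edge matrix in which a chosen disjoint set of "positive" and
  "negative" edges carries a linear behavioral signal,

      edge_e(s) = mu_e + beta_e * zscore(behavior_s) + f_family(s) + eps,

  with beta_e > 0 on positive-signal edges, beta_e < 0 on negative ones,
  i.i.d. Gaussian noise eps, and an optional family-shared offset f that
  exists to demonstrate why family-aware cross-validation matters;
* zero-mean Gaussian node time series with a known precision matrix, for
  testing partial-correlation connectome construction against closed forms.

All generators are pure functions of their spec and seed; a single global
seed fans out to per-stage sub-seeds through a fixed spawn-key counter
(0 = cohort, 1 = edge data, 2 = time series).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from neurocpm.connectome import n_edges
from neurocpm.core import critical_r
from neurocpm.errors import InvalidInputError, InvalidSpecError

__all__ = [
    "GroundTruth",
    "SignalSpec",
    "SyntheticCohortSpec",
    "calibrate_beta",
    "generate_cohort",
    "generate_edge_data",
    "generate_time_series",
]

_STAGE_COHORT = 0
_STAGE_EDGES = 1
_STAGE_TIMESERIES = 2


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass
class SyntheticCohortSpec:
    """Parameters of a family-structured synthetic cohort.

    Defaults mirror the real sample frame: 810 subjects (408 female, hence
    the gender probability), ages 22-37, questionnaire totals on the 0-48
    scale with a conventional mean 32 and SD 6, intelligence as a 0-24
    count-correct score, and a lognormal head-motion summary in mm.  The
    family-size distribution is a convention (mean size 2) chosen so the
    default family count of 400 partitions 810 subjects realistically.
    """

    n_subjects: int = 810
    n_families: int = 400
    family_size_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.30, 2: 0.45, 3: 0.20, 4: 0.05}
    )
    behavior_mean: float = 32.0
    behavior_sd: float = 6.0
    age_range: tuple[int, int] = (22, 37)
    gender_p: float = 408 / 810
    intelligence_mean: float = 17.0
    intelligence_sd: float = 5.0
    motion_median_mm: float = 0.07
    motion_sigma: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise InvalidSpecError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not 1 <= self.n_families <= self.n_subjects:
            raise InvalidSpecError(
                f"need 1 <= n_families <= n_subjects, got n_families={self.n_families}, "
                f"n_subjects={self.n_subjects}"
            )
        sizes = self.family_size_distribution
        if not sizes or any(s < 1 or s != int(s) for s in sizes):
            raise InvalidSpecError("family sizes must be positive integers")
        total = sum(sizes.values())
        if total <= 0 or any(p < 0 for p in sizes.values()):
            raise InvalidSpecError("family-size probabilities must be nonnegative, sum > 0")
        if self.behavior_sd <= 0:
            raise InvalidSpecError("behavior_sd must be positive")
        if not 0.0 <= self.gender_p <= 1.0:
            raise InvalidSpecError("gender_p must lie in [0, 1]")


@dataclass
class SignalSpec:
    """Planted linear edge-behavior signal for a K-node connectome.

    ``beta`` is the edge-weight change (Fisher-z units) per behavior SD on
    every signal edge; ``noise_sd`` is the subject-level edge noise;
    ``family_effect_sd`` adds a Gaussian offset shared by all edges of a
    family's members (default 0).  ``baseline_sd`` scales the per-edge mean
    mu_e ~ N(0, baseline_sd), mimicking the spread of Fisher-z partial
    correlations.
    """

    n_nodes: int = 20
    n_positive_edges: int = 10
    n_negative_edges: int = 10
    beta: float = 0.1
    noise_sd: float = 0.3
    family_effect_sd: float = 0.0
    baseline_sd: float = 0.3
    seed: int = 0

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_nodes)

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise InvalidSpecError(f"n_nodes must be >= 2, got {self.n_nodes}")
        if self.n_positive_edges < 0 or self.n_negative_edges < 0:
            raise InvalidSpecError("signal edge counts must be nonnegative")
        if self.n_positive_edges + self.n_negative_edges > self.n_edges:
            raise InvalidSpecError(
                f"{self.n_positive_edges} + {self.n_negative_edges} signal edges exceed "
                f"the {self.n_edges} available edges for K={self.n_nodes}"
            )
        if self.beta < 0:
            raise InvalidSpecError("beta must be >= 0 (sign is carried by the edge set)")
        if self.noise_sd <= 0:
            raise InvalidSpecError("noise_sd must be positive")
        if self.family_effect_sd < 0 or self.baseline_sd < 0:
            raise InvalidSpecError("family_effect_sd and baseline_sd must be nonnegative")


@dataclass
class GroundTruth:
    """What was planted: signal edge indices, signed effects, latent behavior."""

    positive_edge_indices: np.ndarray
    negative_edge_indices: np.ndarray
    beta_per_edge: np.ndarray
    behavior_latent: np.ndarray


def _family_sizes(spec: SyntheticCohortSpec, rng: np.random.Generator) -> np.ndarray:
    sizes_avail = np.array(sorted(spec.family_size_distribution), dtype=int)
    probs = np.array([spec.family_size_distribution[s] for s in sizes_avail], dtype=float)
    probs = probs / probs.sum()
    sizes = rng.choice(sizes_avail, size=spec.n_families, p=probs)
    # Repair the draw so sizes partition exactly n_subjects, keeping each >= 1.
    diff = spec.n_subjects - int(sizes.sum())
    while diff > 0:
        sizes[rng.integers(spec.n_families)] += 1
        diff -= 1
    while diff < 0:
        i = rng.integers(spec.n_families)
        if sizes[i] > 1:
            sizes[i] -= 1
            diff += 1
    return sizes


def generate_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Generate the phenotype table for a synthetic family-structured cohort.

    Returns a DataFrame with columns ``subject_id``, ``family_id``,
    ``behavior`` (integer, clipped to [0, 48]), ``behavior_latent`` (the
    pre-rounding Gaussian draw), ``age``, ``gender`` (0/1), ``intelligence``
    (integer 0-24) and ``motion`` (mm).  Identical specs give identical
    tables.
    """
    spec.validate()
    rng = _rng(spec.seed, _STAGE_COHORT)
    sizes = _family_sizes(spec, rng)
    n = spec.n_subjects
    width = max(4, len(str(n)))
    fwidth = max(3, len(str(spec.n_families)))
    family_id = np.repeat(
        [f"F{i + 1:0{fwidth}d}" for i in range(spec.n_families)], sizes
    )
    latent = rng.normal(spec.behavior_mean, spec.behavior_sd, size=n)
    behavior = np.clip(np.rint(latent), 0, 48).astype(int)
    age = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n)
    gender = (rng.random(n) < spec.gender_p).astype(int)
    intelligence = np.clip(
        np.rint(rng.normal(spec.intelligence_mean, spec.intelligence_sd, size=n)), 0, 24
    ).astype(int)
    motion = spec.motion_median_mm * np.exp(rng.normal(0.0, spec.motion_sigma, size=n))
    return pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:0{width}d}" for i in range(n)],
            "family_id": family_id,
            "behavior": behavior,
            "behavior_latent": latent,
            "age": age,
            "gender": gender,
            "intelligence": intelligence,
            "motion": motion,
        }
    )


def generate_edge_data(cohort: pd.DataFrame, signal: SignalSpec):
    """Generate the n x E edge matrix with the planted signal for a cohort.

    Edge e of subject s is ``mu_e + beta_e * z_s + f_fam(s) + eps`` where
    ``z`` is the z-scored observed behavior column (all zeros if behavior is
    constant, e.g. n = 1), ``f`` is the family-shared offset and ``eps`` is
    i.i.d. Gaussian noise.  Returns ``(edges, GroundTruth)``.
    """
    signal.validate()
    if len(cohort) == 0:
        raise InvalidInputError("cohort is empty")
    for col in ("behavior", "family_id"):
        if col not in cohort.columns:
            raise InvalidInputError(f"cohort table lacks required column {col!r}")
    rng = _rng(signal.seed, _STAGE_EDGES)
    n = len(cohort)
    e_total = signal.n_edges
    behavior = cohort["behavior"].to_numpy(dtype=float)
    sd = behavior.std()
    z = (behavior - behavior.mean()) / sd if sd > 0 else np.zeros(n)

    chosen = rng.choice(e_total, size=signal.n_positive_edges + signal.n_negative_edges,
                        replace=False)
    pos_idx = np.sort(chosen[: signal.n_positive_edges])
    neg_idx = np.sort(chosen[signal.n_positive_edges:])
    beta_per_edge = np.zeros(e_total)
    beta_per_edge[pos_idx] = signal.beta
    beta_per_edge[neg_idx] = -signal.beta

    mu = rng.normal(0.0, signal.baseline_sd, size=e_total)
    edges = mu[None, :] + np.outer(z, beta_per_edge)
    edges = edges + rng.normal(0.0, signal.noise_sd, size=(n, e_total))
    # Family offsets are drawn last so the same seed with family_effect_sd=0
    # differs from a nonzero setting only by the added offsets.
    if signal.family_effect_sd > 0:
        fam = cohort["family_id"].to_numpy()
        labels, inverse = np.unique(fam, return_inverse=True)
        offsets = rng.normal(0.0, signal.family_effect_sd, size=labels.size)
        edges = edges + offsets[inverse][:, None]

    latent = (cohort["behavior_latent"].to_numpy(dtype=float)
              if "behavior_latent" in cohort.columns else behavior)
    truth = GroundTruth(
        positive_edge_indices=pos_idx,
        negative_edge_indices=neg_idx,
        beta_per_edge=beta_per_edge,
        behavior_latent=latent,
    )
    return edges, truth


def generate_time_series(k: int, t: int, precision: np.ndarray, seed: int = 0) -> np.ndarray:
    """Draw T i.i.d. samples from the zero-mean Gaussian with given precision.

    The K x K ``precision`` matrix must be symmetric positive definite; the
    rows of the returned T x K matrix then have covariance ``inv(precision)``
    and partial correlations ``-P_ij / sqrt(P_ii * P_jj)``.
    """
    p = np.asarray(precision, dtype=float)
    if p.shape != (k, k):
        raise InvalidInputError(f"precision must be {k} x {k}, got shape {p.shape}")
    if not np.allclose(p, p.T, atol=1e-10):
        raise InvalidInputError("precision matrix is not symmetric")
    try:
        chol = np.linalg.cholesky(p)
    except np.linalg.LinAlgError as exc:
        raise InvalidInputError("precision matrix is not positive definite") from exc
    rng = _rng(seed, _STAGE_TIMESERIES)
    zmat = rng.standard_normal((t, k))
    # x = L^{-T} z  has covariance (L L^T)^{-1} = inv(precision)
    return linalg.solve_triangular(chol, zmat.T, lower=True, trans="T").T


def calibrate_beta(target_r: float, n_subjects: int, n_edges_per_tail: int,
                   n_total_edges: int, threshold: float = 0.01,
                   noise_sd: float = 0.3, family_effect_sd: float = 0.0) -> float:
    """Per-edge effect size giving an asymptotic CPM prediction r near target.

    Solves for ``beta`` such that the population correlation between actual
    behavior and the CPM summary-score prediction, accounting for the
    selection step, equals ``target_r``.  The approximation, per tail with
    m = ``n_edges_per_tail`` planted edges out of E = ``n_total_edges``:

    * each planted edge has population correlation
      ``r_e = beta / sqrt(beta^2 + noise_sd^2 + family_effect_sd^2)``;
    * its selection probability at the two-sided threshold follows the
      Fisher-z normal approximation at sample size n, giving an expected
      ``m_sig`` selected signal edges plus ``m_null = (E - 2m) * thr / 2``
      chance selections;
    * the selected-edge sum then correlates with behavior at
      ``m_sig * beta / sqrt((m_sig * beta)^2 + m_tot * noise_sd^2
      + (m_tot * family_effect_sd)^2)`` with ``m_tot = m_sig + m_null``
      (the family offset is shared across a subject's edges, so its
      contribution scales with m_tot squared).

    The mapping is monotone in beta, so a bracketed root-finder suffices.
    Deterministic: no simulation involved.
    """
    if not 0.0 < target_r < 1.0:
        raise InvalidInputError(f"target_r must lie in (0, 1), got {target_r}")
    if n_subjects < 8:
        raise InvalidInputError("calibration needs n_subjects >= 8")
    if n_edges_per_tail < 1 or 2 * n_edges_per_tail > n_total_edges:
        raise InvalidInputError("need 1 <= n_edges_per_tail and 2*m <= E")
    m = n_edges_per_tail
    sigma2 = noise_sd**2 + family_effect_sd**2
    z_crit = np.arctanh(critical_r(threshold, n_subjects - 2))
    z_sd = 1.0 / np.sqrt(n_subjects - 3)
    m_null = (n_total_edges - 2 * m) * threshold / 2.0

    def predicted_r(beta: float) -> float:
        r_e = beta / np.sqrt(beta**2 + sigma2)
        z_e = np.arctanh(min(r_e, 1 - 1e-12))
        p_sel = stats.norm.sf((z_crit - z_e) / z_sd)
        m_sig = m * p_sel
        m_tot = m_sig + m_null
        if m_tot <= 0:
            return 0.0
        signal = m_sig * beta
        noise_var = m_tot * noise_sd**2 + (m_tot * family_effect_sd) ** 2
        return float(signal / np.sqrt(signal**2 + noise_var))

    hi = 10.0 * np.sqrt(sigma2)
    while predicted_r(hi) < target_r:
        hi *= 2.0
        if hi > 1e6:
            raise InvalidInputError("calibration failed to bracket the target r")
    return float(optimize.brentq(lambda b: predicted_r(b) - target_r, 1e-9, hi, xtol=1e-10))
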