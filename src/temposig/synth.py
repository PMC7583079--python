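"""Seeded generators of temporal matrices with known structure.

These generators emulate the structure of a temporal oxidative-PTM occupancy
study — roughly 1600 variables over 6 time points (days 1, 3, 5, 7, 10, 14),
4 replicates per condition, log-2 treated/control ratios, scattered missing
cells — with full ground truth (cluster labels, noiseless signals, missing
mask), so every stage of the platform is testable without any download.

The five default cluster templates mirror the qualitative temporal patterns
the platform is designed to separate: continual descent, continual ascent,
early descent then plateau, late accelerating ascent, and an early ascent
relapsing to baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TemporalMatrix
from .errors import ParameterError

DEFAULT_TIME_POINTS = (1.0, 3.0, 5.0, 7.0, 10.0, 14.0)


def default_templates(time_points=DEFAULT_TIME_POINTS, K: int = 5,
                      amplitude: float = 1.0) -> np.ndarray:
    """K x n base temporal profiles on the log-ratio scale.

    Each template is scaled to standard deviation `amplitude` over the time
    axis, so the generator's signal-to-noise ratio (amplitude / noise sd)
    holds uniformly across clusters rather than depending on a template's
    shape.
    """
    t = np.asarray(time_points, dtype=float)
    u = (t - t[0]) / (t[-1] - t[0])  # normalized time in [0, 1]
    mid = 0.45
    shapes = [
        1.0 - 2.0 * u,                                    # continual descent
        2.0 * u - 1.0,                                    # continual ascent
        np.maximum(-1.0, 1.0 - 2.0 * u / mid),            # descent then plateau
        np.where(u < mid, -0.3 * u / mid,
                 -0.3 + 1.3 * ((u - mid) / (1 - mid)) ** 2),  # late ascent
        np.sin(np.pi * np.minimum(u / 0.9, 1.0)),         # ascent then relapse
    ]
    templates = np.array(shapes[:K] if K <= 5 else shapes)
    if K > 5:  # extra clusters: phase-shifted sinusoids, pairwise distinct
        extra = [np.cos(np.pi * (j + 2) * u) for j in range(K - 5)]
        templates = np.vstack([templates, extra])
    sd = templates.std(axis=1, keepdims=True)
    return amplitude * templates / sd


@dataclass
class SyntheticSpec:
    """Parameters of the clustered time-course generator."""

    m: int = 1600
    K: int = 5
    time_points: tuple = DEFAULT_TIME_POINTS
    templates: np.ndarray | None = None
    snr: float = 4.0              # template amplitude / noise sd
    amplitude: float = 1.0
    missing_rate: float = 0.15
    spike_noise_fraction: float = 0.1
    n_replicates: int = 4
    min_observed: int = 4         # splines need 4 points per row
    seed: int = 20200603

    def __post_init__(self):
        self.time_points = tuple(float(t) for t in self.time_points)
        if self.templates is None:
            self.templates = default_templates(self.time_points, self.K,
                                               self.amplitude)
        self.templates = np.asarray(self.templates, dtype=float)
        n = len(self.time_points)
        if self.templates.shape != (self.K, n):
            raise ParameterError("templates must be K x n")
        for a in range(self.K):
            for b in range(a + 1, self.K):
                if np.allclose(self.templates[a], self.templates[b]):
                    raise ParameterError("templates must be pairwise distinct")
        if not (self.m >= 1 and 1 <= self.K <= self.m and n >= 2):
            raise ParameterError("invalid m/K/n")
        if not 0 <= self.missing_rate < 1:
            raise ParameterError("missing_rate must lie in [0, 1)")
        if not 0 <= self.spike_noise_fraction < 1:
            raise ParameterError("spike_noise_fraction must lie in [0, 1)")
        if self.snr <= 0:
            raise ParameterError("snr must be positive")
        if self.min_observed < 1:
            raise ParameterError("min_observed must be >= 1")

    @property
    def n(self) -> int:
        return len(self.time_points)

    @property
    def noise_sd(self) -> float:
        return float(self.amplitude / self.snr)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated matrix (label 0 = noise row)."""

    true_labels: np.ndarray
    noiseless_matrix: np.ndarray
    missing_mask: np.ndarray

    def to_dict(self) -> dict:
        return {
            "true_labels": self.true_labels.tolist(),
            "noiseless_matrix": self.noiseless_matrix.tolist(),
            "missing_mask": self.missing_mask.tolist(),
        }


def generate_clustered_timecourses(spec: SyntheticSpec):
    """Generate a matrix of noisy template rows plus pure-noise spike rows.

    Row i is its cluster's template plus i.i.d. Gaussian noise of sd
    amplitude/snr; a `spike_noise_fraction` of rows are pure noise with true
    label 0. Missing cells are dropped uniformly at random at `missing_rate`,
    subject to every row keeping at least `min_observed` observed cells
    (capped at n). Deterministic given the seed.

    Returns
    -------
    (TemporalMatrix, SyntheticTruth)
    """
    rng = np.random.default_rng(spec.seed)
    m, n, K = spec.m, spec.n, spec.K
    min_obs = min(spec.min_observed, n)
    if min_obs < 1:
        raise ParameterError("min_observed must be >= 1")

    n_spikes = int(round(spec.spike_noise_fraction * m))
    labels = np.zeros(m, dtype=int)
    member_rows = np.arange(n_spikes, m)
    labels[member_rows] = 1 + (np.arange(len(member_rows)) % K)
    rng.shuffle(labels)

    noiseless = np.zeros((m, n))
    for k in range(1, K + 1):
        noiseless[labels == k] = spec.templates[k - 1]
    values = noiseless + rng.normal(0.0, spec.noise_sd, size=(m, n))
    # spike rows: no temporal coherence, but the marginal scale of signal
    # rows (a near-constant row would not have survived the fold-change
    # pre-filter, so it could not occur in the matrices this emulates)
    spike_sd = float(np.sqrt(spec.amplitude ** 2 + spec.noise_sd ** 2))
    spikes = labels == 0
    values[spikes] = rng.normal(0.0, spike_sd, size=(int(spikes.sum()), n))

    missing = rng.random((m, n)) < spec.missing_rate
    for i in range(m):
        excess = int(missing[i].sum()) - (n - min_obs)
        if excess > 0:
            hit = np.flatnonzero(missing[i])
            restore = rng.choice(hit, size=excess, replace=False)
            missing[i, restore] = False
    values = np.where(missing, np.nan, values)

    ids = [f"V{i + 1:05d}" for i in range(m)]
    matrix = TemporalMatrix(values, np.asarray(spec.time_points), ids,
                            {"log_base": "2", "source": "synthetic"})
    return matrix, SyntheticTruth(labels, noiseless, missing)


def generate_null_matrix(m: int, n: int, seed: int = 20200603) -> TemporalMatrix:
    """i.i.d. standard-Gaussian matrix with no missing cells (null calibration)."""
    if m < 2 or n < 2:
        raise ParameterError("m and n must be >= 2")
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((m, n))
    ids = [f"N{i + 1:05d}" for i in range(m)]
    return TemporalMatrix(values, np.arange(1, n + 1, dtype=float), ids,
                          {"source": "synthetic-null"})


def generate_replicate_table(spec: SyntheticSpec,
                             replicate_noise_sd: float = 0.05,
                             log_base: float = 2.0) -> pd.DataFrame:
    """Long-format replicate-level occupancies consistent with the templates.

    Control occupancies are drawn from a positive baseline; treated
    occupancies are control * base**template * multiplicative log-normal
    replicate noise, so `collapse_replicates` recovers the noiseless template
    matrix as the replicate noise vanishes (exactly, at zero noise).
    Spike rows use a zero template (unit ratios).
    """
    if spec.n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    rng = np.random.default_rng(spec.seed + 1)
    m, K = spec.m, spec.K
    n_spikes = int(round(spec.spike_noise_fraction * m))
    labels = np.zeros(m, dtype=int)
    member_rows = np.arange(n_spikes, m)
    labels[member_rows] = 1 + (np.arange(len(member_rows)) % K)
    rng.shuffle(labels)

    records = []
    for i in range(m):
        vid = f"V{i + 1:05d}"
        template = (spec.templates[labels[i] - 1] if labels[i] > 0
                    else np.zeros(spec.n))
        for j, t in enumerate(spec.time_points):
            for rep in range(1, spec.n_replicates + 1):
                control = rng.uniform(0.2, 0.8)
                noise = (np.exp(rng.normal(0.0, replicate_noise_sd))
                         if replicate_noise_sd > 0 else 1.0)
                treated = control * log_base ** template[j] * noise
                records.append((vid, t, "control", rep, control))
                records.append((vid, t, "treated", rep, treated))
    return pd.DataFrame(records, columns=["variable_id", "time", "condition",
                                          "replicate", "occupancy"])


def generate_annotation(spec: SyntheticSpec, n_proteins: int = 400,
                        n_functions: int = 10,
                        functions_per_protein: tuple = (1, 3),
                        seed: int | None = None):
    """Random variable->protein and protein->function maps for enrichment tests.

    Proteins host a variable number of events; each protein carries between
    `functions_per_protein[0]` and `[1]` of `n_functions` labelled BF terms.
    """
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    from .enrich import AnnotationMap

    proteins = [f"P{i + 1:04d}" for i in range(n_proteins)]
    functions = [f"BF{i + 1}" for i in range(n_functions)]
    v2p = {f"V{i + 1:05d}": proteins[rng.integers(n_proteins)]
           for i in range(spec.m)}
    lo, hi = functions_per_protein
    p2f = {}
    for pr in proteins:
        k = int(rng.integers(lo, hi + 1))
        p2f[pr] = set(rng.choice(functions, size=k, replace=False).tolist())
    return AnnotationMap(v2p, p2f)
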