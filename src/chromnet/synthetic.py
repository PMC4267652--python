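"""Synthetic promoter-level count data with known interaction networks.

The generator produces the statistical structure the inference assumes:

* chromatin modifiers (CMs) organized in complexes — same-complex tracks
  share a latent factor and are therefore strongly correlated;
* histone modification (HM) log-signals that are sparse, signed linear
  combinations of the CM log-signals plus Gaussian noise;
* expression replicates whose log-signal is a linear combination of the
  HM log-signals plus Gaussian noise;
* a per-promoter coverage bias shared by all tracks and captured by an
  input-control track — exactly the nuisance the median-ratio
  normalization is designed to remove;
* two "cell types" (conditions) sharing all interaction weights but
  differing in per-CM activity multipliers.

Generative scheme (fixed; tests rely on it). Per promoter:

1. coverage bias ``b ~ lognormal(0, input_bias_sd)``;
2. CM latent log-signal ``z_c = sqrt(rho) * f_g + sqrt(1 - rho) * e_c``
   with ``f_g`` the complex factor of c's complex and ``e_c`` independent
   standard normal, so same-complex pairs have correlation ``rho``;
   in condition k the latent is multiplied by ``activity[k, c]``;
3. HM latent ``h = W z + N(0, noise_sd_hm)`` with ``W`` the sparse signed
   CM->HM weight matrix;
4. expression replicate latent ``y_r = v . h + N(0, noise_sd_expr)``;
5. observed counts ``~ Poisson(count_depth * b * exp(latent))`` per track,
   and input counts ``~ Poisson(count_depth * b)``.

Latent draws in steps 1-4 depend only on the truth network's seed, so two
conditions with identical activity multipliers differ only in Poisson
count noise. The latent log-signals are attached to the returned matrix
(``SignalMatrix.latent``) for use as test oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError
from .signal_matrix import (
    ROLE_CM,
    ROLE_EXPRESSION,
    ROLE_HM,
    ROLE_INPUT,
    STATE_RAW,
    SignalMatrix,
)

INPUT_TRACK = "input"
EXPRESSION_REPLICATES = ("expr_rep1", "expr_rep2")
CONDITIONS = ("A", "B")

#: spread of the per-CM activity multipliers in condition "B"
#: (lognormal sigma on the multiplier; condition "A" is all ones)
ACTIVITY_LOG_SD = 0.2


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the synthetic study.

    Defaults define the standard study conditions used throughout the test
    suite: 5000 promoters, 20 CMs in 4 complexes, 8 HMs, edge density 0.2.
    ``within_complex_corr`` is the latent correlation of same-complex CM
    pairs; ``count_depth`` is the mean input-control reads per promoter
    window; ``input_bias_sd`` the log-scale SD of the shared coverage bias.
    Noise SDs are on the latent log-signal scale, calibrated so that
    cross-validated HM-on-CM R^2 lands in the 0.5-0.9 range typical of
    promoter ChIP-Seq co-occupancy data.
    """

    n_promoters: int = 5000
    n_cm: int = 20
    n_hm: int = 8
    n_complexes: int = 4
    within_complex_corr: float = 0.7
    edge_density: float = 0.2
    count_depth: float = 50.0
    input_bias_sd: float = 0.5
    noise_sd_hm: float = 0.6
    noise_sd_expr: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_promoters, self.n_cm, self.n_hm, self.n_complexes) < 1:
            raise ParameterError("counts must be positive integers")
        if self.n_complexes > self.n_cm:
            raise ParameterError("n_complexes cannot exceed n_cm")
        if not 0.0 <= self.within_complex_corr < 1.0:
            raise ParameterError("within_complex_corr must lie in [0, 1)")
        if not 0.0 < self.edge_density <= 1.0:
            raise ParameterError("edge_density must lie in (0, 1]")
        if self.count_depth < 0:
            raise ParameterError("count_depth must be nonnegative")
        if self.input_bias_sd < 0 or self.noise_sd_hm < 0 or self.noise_sd_expr < 0:
            raise ParameterError("noise SDs must be nonnegative")


@dataclass
class TruthNetwork:
    """Ground-truth bipartite CM->HM network behind a synthetic dataset."""

    cm_names: list[str]
    hm_names: list[str]
    complex_assignment: dict[str, int]
    cm_hm_weights: np.ndarray  # (n_hm, n_cm)
    hm_expression_weights: np.ndarray  # (n_hm,)
    noise_sd_hm: float
    noise_sd_expr: float
    condition_activity: dict[str, dict[str, float]]  # condition -> CM -> mult
    seed: int

    def __post_init__(self) -> None:
        self.cm_hm_weights = np.asarray(self.cm_hm_weights, dtype=float)
        self.hm_expression_weights = np.asarray(
            self.hm_expression_weights, dtype=float
        )
        if self.cm_hm_weights.shape != (len(self.hm_names), len(self.cm_names)):
            raise ParameterError("cm_hm_weights shape mismatch")
        if not np.all(np.isfinite(self.cm_hm_weights)):
            raise ParameterError("weights must be finite")
        if np.any((self.cm_hm_weights != 0).sum(axis=1) == 0):
            raise ParameterError("every HM needs at least one incoming edge")
        if set(self.complex_assignment) != set(self.cm_names):
            raise ParameterError("complex_assignment must cover every CM")

    # -- edge views -------------------------------------------------------

    def true_edges(self) -> set[tuple[str, str]]:
        """All (cm, hm) pairs with a nonzero weight."""
        hm_idx, cm_idx = np.nonzero(self.cm_hm_weights)
        return {
            (self.cm_names[c], self.hm_names[h])
            for h, c in zip(hm_idx, cm_idx)
        }

    def edge_weight(self, cm: str, hm: str) -> float:
        return float(
            self.cm_hm_weights[self.hm_names.index(hm), self.cm_names.index(cm)]
        )

    def top_tercile_edges(self) -> set[tuple[str, str]]:
        """True edges whose |weight| is in the top third of true edges."""
        edges = sorted(
            self.true_edges(),
            key=lambda e: abs(self.edge_weight(*e)),
            reverse=True,
        )
        n_top = max(1, int(np.ceil(len(edges) / 3)))
        return set(edges[:n_top])

    # -- I/O --------------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cm_names": self.cm_names,
            "hm_names": self.hm_names,
            "complex_assignment": self.complex_assignment,
            "cm_hm_weights": self.cm_hm_weights.tolist(),
            "hm_expression_weights": self.hm_expression_weights.tolist(),
            "noise_sd_hm": self.noise_sd_hm,
            "noise_sd_expr": self.noise_sd_expr,
            "condition_activity": self.condition_activity,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthNetwork":
        payload = json.loads(Path(path).read_text())
        payload["cm_hm_weights"] = np.asarray(payload["cm_hm_weights"])
        payload["hm_expression_weights"] = np.asarray(
            payload["hm_expression_weights"]
        )
        return cls(**payload)


def generate_truth(params: SimulationParams) -> TruthNetwork:
    """Draw a ground-truth network for the given simulation parameters.

    CMs are partitioned round-robin into ``n_complexes`` groups. Each
    CM->HM weight is nonzero with probability ``edge_density``; nonzero
    magnitudes are uniform on [0.4, 1.2] with random sign. An HM left with
    no incoming edge gets one forced at a random CM, so every HM is a
    (noisy) function of at least one CM. HM->expression weights are
    uniform on [0.3, 1.0], positive: expression is driven by the marks.
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    cm_names = [f"CM{i + 1:02d}" for i in range(params.n_cm)]
    hm_names = [f"HM{i + 1:02d}" for i in range(params.n_hm)]
    complex_assignment = {
        cm: i % params.n_complexes for i, cm in enumerate(cm_names)
    }

    present = rng.random((params.n_hm, params.n_cm)) < params.edge_density
    for h in range(params.n_hm):
        if not present[h].any():
            present[h, rng.integers(params.n_cm)] = True
    magnitude = rng.uniform(0.4, 1.2, size=present.shape)
    sign = rng.choice([-1.0, 1.0], size=present.shape)
    weights = np.where(present, magnitude * sign, 0.0)

    # Expression weights are scaled so the expression latent has unit
    # variance in condition A (analytic: CM latent covariance is rho within
    # a complex, 1 on the diagonal); keeps simulated tag counts on a
    # realistic scale regardless of network size.
    v_raw = rng.uniform(0.3, 1.0, size=params.n_hm)
    sigma_cm = np.zeros((params.n_cm, params.n_cm))
    groups = np.array([complex_assignment[cm] for cm in cm_names])
    sigma_cm[groups[:, None] == groups[None, :]] = params.within_complex_corr
    np.fill_diagonal(sigma_cm, 1.0)
    cov_h = weights @ sigma_cm @ weights.T + params.noise_sd_hm**2 * np.eye(
        params.n_hm
    )
    hm_expression_weights = v_raw / np.sqrt(v_raw @ cov_h @ v_raw)

    activity_b = np.exp(rng.normal(0.0, ACTIVITY_LOG_SD, size=params.n_cm))
    condition_activity = {
        "A": {cm: 1.0 for cm in cm_names},
        "B": {cm: float(a) for cm, a in zip(cm_names, activity_b)},
    }

    return TruthNetwork(
        cm_names=cm_names,
        hm_names=hm_names,
        complex_assignment=complex_assignment,
        cm_hm_weights=weights,
        hm_expression_weights=hm_expression_weights,
        noise_sd_hm=params.noise_sd_hm,
        noise_sd_expr=params.noise_sd_expr,
        condition_activity=condition_activity,
        seed=params.seed,
    )


def _latent_signals(
    truth: TruthNetwork, params: SimulationParams, condition: str
) -> tuple[pd.DataFrame, np.ndarray]:
    """Latent log-signals for all tracks plus the coverage bias.

    All Gaussian draws use a stream derived only from the truth seed, so
    conditions differ solely through the activity multipliers (and,
    downstream, independent count noise).
    """
    rng = np.random.default_rng([truth.seed, 1])
    n = params.n_promoters
    rho = params.within_complex_corr

    bias = np.exp(rng.normal(0.0, params.input_bias_sd, size=n))

    factors = rng.normal(size=(n, params.n_complexes))
    indiv = rng.normal(size=(n, len(truth.cm_names)))
    cm_latent = np.empty_like(indiv)
    for j, cm in enumerate(truth.cm_names):
        g = truth.complex_assignment[cm]
        cm_latent[:, j] = np.sqrt(rho) * factors[:, g] + np.sqrt(1 - rho) * indiv[:, j]

    activity = np.array(
        [truth.condition_activity[condition][cm] for cm in truth.cm_names]
    )
    cm_latent = cm_latent * activity

    hm_noise = rng.normal(0.0, 1.0, size=(n, len(truth.hm_names)))
    hm_latent = cm_latent @ truth.cm_hm_weights.T + truth.noise_sd_hm * hm_noise

    expr_latent = {}
    for rep in EXPRESSION_REPLICATES:
        noise = rng.normal(0.0, 1.0, size=n)
        expr_latent[rep] = (
            hm_latent @ truth.hm_expression_weights + truth.noise_sd_expr * noise
        )

    promoters = [f"prom{i + 1:05d}" for i in range(n)]
    latent = pd.DataFrame(
        {
            **{cm: cm_latent[:, j] for j, cm in enumerate(truth.cm_names)},
            **{hm: hm_latent[:, j] for j, hm in enumerate(truth.hm_names)},
            **expr_latent,
        },
        index=promoters,
    )
    return latent, bias


def simulate_counts(
    truth: TruthNetwork, params: SimulationParams, condition: str
) -> SignalMatrix:
    """Observe the latent model as Poisson counts for one condition.

    Returns a raw-count SignalMatrix with CM, HM, two expression-replicate
    tracks and one input-control track; the latent log-signals are
    attached for oracle access.
    """
    if condition not in truth.condition_activity:
        raise SchemaError(
            f"unknown condition {condition!r}; have "
            f"{sorted(truth.condition_activity)}"
        )
    latent, bias = _latent_signals(truth, params, condition)
    cond_index = sorted(truth.condition_activity).index(condition)
    rng = np.random.default_rng([truth.seed, 2, cond_index])

    counts = {}
    for track in latent.columns:
        mean = params.count_depth * bias * np.exp(latent[track].to_numpy())
        counts[track] = rng.poisson(mean)
    counts[INPUT_TRACK] = rng.poisson(params.count_depth * bias)

    roles = {cm: ROLE_CM for cm in truth.cm_names}
    roles.update({hm: ROLE_HM for hm in truth.hm_names})
    roles.update({rep: ROLE_EXPRESSION for rep in EXPRESSION_REPLICATES})
    roles[INPUT_TRACK] = ROLE_INPUT

    data = pd.DataFrame(counts, index=latent.index)
    return SignalMatrix(data=data, roles=roles, state=STATE_RAW, latent=latent)


def make_fixture_pair(
    params: SimulationParams,
) -> tuple[TruthNetwork, SignalMatrix, SignalMatrix]:
    """One truth network observed in two conditions ("cell types").

    Both matrices share track names and interaction weights; condition "B"
    differs from "A" through per-CM activity multipliers and independent
    count noise.
    """
    truth = generate_truth(params)
    sm_a = simulate_counts(truth, params, "A")
    sm_b = simulate_counts(truth, params, "B")
    return truth, sm_a, sm_b
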