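"""Causal inference of multisensory speech (CIMS) with error-driven recalibration.

The model places speech tokens in a two-dimensional representational space whose
x-axis carries auditory features and whose y-axis carries visual features.  Each
presentation gives rise to Gaussian encoding distributions: the auditory
representation A is reliable along x but uncertain along y, the visual
representation V the reverse.  Reliability (inverse-variance) weighting pools A and
V; causal inference then mixes the pooled representation with A according to the
observer's probability ``p_common`` that the face and voice share a cause (C = 1),
yielding the integrated audiovisual representation AV.  A percept is the token
whose mean is nearest to the encoded location.

Recalibration: on each audiovisual trial the distance between the encoded A and AV
locations is an error signal.  Across the first exposure day the error drives the
auditory representation to a new location A' on the segment from A to AV, the shift
fraction proportional to the day's McGurk (fusion) percept count.  Participants who
never fuse have A' = A.  Auditory-only post-test percepts are simulated (or
computed in closed form) from A'.

With the default geometry — token means collinear and equidistant on the diagonal —
nearest-mean classification depends only on the projection onto the token line, so
every fusion probability has an exact univariate Gaussian closed form.  That closed
form serves as the oracle for the trial-level simulator.

All distributions are axis-aligned; encoding covariances are fixed across
participants and are never fit to data.  Individual differences enter only through
``p_common`` and the day-1 fusion fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .dataset_io import StimulusSpec

__all__ = [
    "RepresentationalSpace",
    "EncodingDistribution",
    "ParticipantModel",
    "ModelConfig",
    "pool_av",
    "integrate_causal",
    "classify_point",
    "simulate_exposure_trial",
    "simulate_exposure_trials",
    "fit_p_common",
    "shift_auditory",
    "posttest_fusion_probability",
    "token_probability",
    "simulate_posttest",
    "shift_fraction_for_fusion_probability",
    "predict_cohort",
]


@dataclass(frozen=True)
class RepresentationalSpace:
    """Token labels and their 2-D means; percepts are nearest-mean classifications.

    The space is shared across participants.  ``fusion_token`` names the token whose
    region defines a fusion percept (it must lie strictly between the auditory and
    visual tokens for a McGurk pairing).  Ties in the nearest-mean rule break by
    token order.
    """

    tokens: tuple[str, ...]
    means: np.ndarray  # shape (k, 2)
    fusion_token: str | None = None

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        object.__setattr__(self, "means", means)
        if means.shape != (len(self.tokens), 2):
            raise ValueError("means must be (n_tokens, 2)")
        if len(self.tokens) < 2:
            raise ValueError("a space needs at least two tokens")
        if len({tuple(m) for m in means}) != len(self.tokens):
            raise ValueError("token means must be distinct")
        if self.fusion_token is not None and self.fusion_token not in self.tokens:
            raise ValueError(f"unknown fusion token {self.fusion_token!r}")

    def index(self, token: str) -> int:
        return self.tokens.index(token)

    @property
    def line_direction(self) -> np.ndarray | None:
        """Unit direction of the token line if all means are collinear, else None."""
        d = self.means - self.means[0]
        norms = np.linalg.norm(d, axis=1)
        i = int(np.argmax(norms))
        if norms[i] == 0:
            return None
        u = d[i] / norms[i]
        residual = d - np.outer(d @ u, u)
        if np.max(np.abs(residual)) > 1e-9:
            return None
        return u


@dataclass(frozen=True)
class EncodingDistribution:
    """Axis-aligned 2-D Gaussian over the representational space."""

    center: np.ndarray  # (2,)
    variances: np.ndarray  # (2,) diagonal of the covariance
    modality: str = "A"  # A | V | pooled | AV | A_shifted

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float)
        variances = np.asarray(self.variances, dtype=float)
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "variances", variances)
        if center.shape != (2,) or variances.shape != (2,):
            raise ValueError("center and variances must be 2-vectors")
        if not np.all(variances > 0):
            raise ValueError("variances must be positive")
        if self.modality == "A" and not variances[1] > variances[0]:
            raise ValueError("auditory encodings must be more uncertain along y")
        if self.modality == "V" and not variances[0] > variances[1]:
            raise ValueError("visual encodings must be more uncertain along x")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, 2))
        return self.center + np.sqrt(self.variances) * z


@dataclass(frozen=True)
class ParticipantModel:
    """Fitted per-participant model state."""

    participant_id: str
    p_common: float
    day1_fusion_fraction: float
    a_prime: EncodingDistribution

    def __post_init__(self) -> None:
        if not 0 <= self.p_common <= 1:
            raise ValueError("p_common must be in [0, 1]")
        if not 0 <= self.day1_fusion_fraction <= 1:
            raise ValueError("day1_fusion_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ModelConfig:
    """Model geometry and fitting conventions.

    The token line runs along the diagonal with means at (0,0), (1,1), (2,2) in
    the order auditory / fusion / visual, so the fusion token lies strictly between
    the other two.  Encoding variances are axis-aligned and shared by all
    participants; their anisotropy (A reliable along x, V along y) is structural,
    their magnitude a calibration choice: the defaults put the unshifted auditory
    representation ~5.8 projected SDs from the fusion region, making pre-test
    fusion reports essentially impossible (mass < 1e-8), as observed.
    """

    auditory_variances: tuple[float, float] = (0.005, 0.025)
    visual_variances: tuple[float, float] = (0.025, 0.005)
    token_spacing: float = 1.0
    integration: str = "average"  # "average" | "select"
    target_stimulus: str = "S1"
    n_sim_trials: int = 10_000

    def space_for(self, stim: StimulusSpec) -> RepresentationalSpace:
        """Representational space of a McGurk pairing (auditory/fusion/visual)."""
        if stim.visual_token is None or stim.expected_fusion_token is None:
            raise ValueError("space_for needs an incongruent audiovisual stimulus")
        s = self.token_spacing
        return RepresentationalSpace(
            tokens=(stim.auditory_token, stim.expected_fusion_token, stim.visual_token),
            means=np.array([[0.0, 0.0], [s, s], [2 * s, 2 * s]]),
            fusion_token=stim.expected_fusion_token,
        )

    def encoders_for(
        self, space: RepresentationalSpace
    ) -> tuple[EncodingDistribution, EncodingDistribution]:
        """The fixed A and V encoding distributions in a pairing's space."""
        a = EncodingDistribution(space.means[0], self.auditory_variances, "A")
        v = EncodingDistribution(space.means[-1], self.visual_variances, "V")
        return a, v


# ---------------------------------------------------------------------------
# integration


def pool_av(a: EncodingDistribution, v: EncodingDistribution) -> EncodingDistribution:
    """Reliability-weighted (inverse-variance) pooling of A and V, per axis.

    Infinite variance on an axis contributes zero precision, so a totally
    unreliable cue drops out: as both visual variances -> inf, pooled -> A.
    """
    if np.any(np.asarray(a.variances) <= 0) or np.any(np.asarray(v.variances) <= 0):
        raise ValueError("variances must be positive")
    with np.errstate(divide="ignore"):
        pa = 1.0 / np.asarray(a.variances, dtype=float)
        pv = 1.0 / np.asarray(v.variances, dtype=float)
    prec = pa + pv
    center = (a.center * pa + v.center * pv) / prec
    return EncodingDistribution(center, 1.0 / prec, "pooled")


def integrate_causal(
    a: EncodingDistribution,
    pooled: EncodingDistribution,
    p_common: float,
    convention: str = "average",
) -> EncodingDistribution:
    """Combine the common-cause (pooled) and separate-cause (A) hypotheses.

    ``average`` (default): centers and covariances mix linearly in ``p_common``
    (model averaging).  ``select``: the higher-weighted hypothesis is taken whole
    (model selection; ties at 0.5 go to the common-cause hypothesis).
    """
    if not 0 <= p_common <= 1:
        raise ValueError("p_common must be in [0, 1]")
    if convention == "average":
        center = p_common * pooled.center + (1 - p_common) * a.center
        variances = p_common * pooled.variances + (1 - p_common) * a.variances
    elif convention == "select":
        chosen = pooled if p_common >= 0.5 else a
        center, variances = chosen.center, chosen.variances
    else:
        raise ValueError(f"unknown integration convention {convention!r}")
    return EncodingDistribution(center, variances, "AV")


def classify_point(pt: np.ndarray, space: RepresentationalSpace) -> str:
    """Nearest-mean token for one point; ties break by token order."""
    d2 = np.sum((space.means - np.asarray(pt, dtype=float)) ** 2, axis=1)
    return space.tokens[int(np.argmin(d2))]


def _classify_many(points: np.ndarray, space: RepresentationalSpace) -> np.ndarray:
    d2 = ((points[:, None, :] - space.means[None, :, :]) ** 2).sum(axis=2)
    return np.asarray(space.tokens)[np.argmin(d2, axis=1)]


# ---------------------------------------------------------------------------
# closed-form token masses


def token_probability(
    dist: EncodingDistribution, space: RepresentationalSpace, token: str
) -> float:
    """Probability that a sample from ``dist`` classifies as ``token``.

    Exact when the token means are collinear: nearest-mean regions are then slabs
    perpendicular to the token line, so the mass is a univariate Gaussian interval
    of the projected distribution.  Non-collinear spaces fall back to deterministic
    Gauss-Hermite quadrature.
    """
    u = space.line_direction
    if u is not None:
        proj = space.means @ u
        m = float(dist.center @ u)
        s = float(np.sqrt(dist.variances @ (u**2)))
        t = proj[space.index(token)]
        below = proj[proj < t]
        above = proj[proj > t]
        lo = (t + below.max()) / 2 if below.size else -np.inf
        hi = (t + above.min()) / 2 if above.size else np.inf
        return float(norm.cdf((hi - m) / s) - norm.cdf((lo - m) / s))
    # general 2-D fallback: tensor-product Gauss-Hermite over the distribution
    nodes, weights = np.polynomial.hermite_e.hermegauss(101)
    sx, sy = np.sqrt(dist.variances)
    xs = dist.center[0] + sx * nodes
    ys = dist.center[1] + sy * nodes
    grid = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
    w = np.outer(weights, weights).reshape(-1) / (2 * np.pi)
    labels = _classify_many(grid, space)
    return float(w[labels == token].sum())


def posttest_fusion_probability(
    a_prime: EncodingDistribution,
    space: RepresentationalSpace,
    token: str | None = None,
) -> float:
    """Closed-form probability of a fusion percept in an auditory-only test."""
    token = token if token is not None else space.fusion_token
    if token is None:
        raise ValueError("space has no fusion token")
    return token_probability(a_prime, space, token)


# ---------------------------------------------------------------------------
# trial-level simulation


def simulate_exposure_trials(
    a: EncodingDistribution,
    v: EncodingDistribution,
    p_common: float,
    space: RepresentationalSpace,
    n_trials: int,
    rng: np.random.Generator,
    convention: str = "average",
    shared_noise: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate audiovisual exposure trials.

    Each trial draws an encoded A location and an encoded AV location (from the
    integrated distribution); the percept is the nearest token to the encoded AV
    location, and the error signal is the Euclidean distance between the two
    encoded locations.  With ``shared_noise`` the two locations share the same
    standardized noise draw (common random numbers), so at ``p_common = 0`` the
    encodings coincide and the error is exactly zero.

    Returns (percepts, errors), arrays of length ``n_trials``.
    """
    av = integrate_causal(a, pool_av(a, v), p_common, convention)
    z = rng.standard_normal((n_trials, 2))
    enc_a = a.center + np.sqrt(a.variances) * z
    z_av = z if shared_noise else rng.standard_normal((n_trials, 2))
    enc_av = av.center + np.sqrt(av.variances) * z_av
    percepts = _classify_many(enc_av, space)
    errors = np.linalg.norm(enc_av - enc_a, axis=1)
    return percepts, errors


def simulate_exposure_trial(
    a: EncodingDistribution,
    v: EncodingDistribution,
    p_common: float,
    space: RepresentationalSpace,
    rng: np.random.Generator,
    convention: str = "average",
    shared_noise: bool = True,
) -> tuple[str, float]:
    """One audiovisual exposure trial: (percept, error signal)."""
    percepts, errors = simulate_exposure_trials(
        a, v, p_common, space, 1, rng, convention, shared_noise
    )
    return str(percepts[0]), float(errors[0])


def simulate_posttest(
    a_prime: EncodingDistribution,
    space: RepresentationalSpace,
    n_trials: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate auditory-only test percepts by sampling A' and classifying.

    The empirical fusion fraction converges to
    :func:`posttest_fusion_probability` as ``n_trials`` grows.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return _classify_many(a_prime.sample(n_trials, rng), space)


# ---------------------------------------------------------------------------
# fitting


def fit_p_common(
    observed_exposure_fusion_fraction: float,
    a: EncodingDistribution,
    v: EncodingDistribution,
    space: RepresentationalSpace,
    convention: str = "average",
    tol: float = 1e-12,
) -> float:
    """Invert the exposure fusion rate to the common-cause probability.

    The closed-form fusion probability of the integrated AV distribution is a
    monotone function of ``p_common`` under sane geometry; the observed fraction is
    matched by bisection and clamped to 0/1 outside the attainable range.
    """
    q = observed_exposure_fusion_fraction
    if not 0 <= q <= 1:
        raise ValueError("observed fraction must be in [0, 1]")
    pooled = pool_av(a, v)

    def f(p: float) -> float:
        av = integrate_causal(a, pooled, p, convention)
        return posttest_fusion_probability(av, space)

    grid = np.linspace(0.0, 1.0, 41)
    vals = np.array([f(p) for p in grid])
    if np.any(np.diff(vals) < -1e-9):
        raise ValueError(
            "fusion probability is not monotone in p_common; degenerate geometry"
        )
    if q <= vals[0]:
        return 0.0
    if q >= vals[-1]:
        return 1.0
    return float(brentq(lambda p: f(p) - q, 0.0, 1.0, xtol=tol))


def shift_auditory(
    a: EncodingDistribution,
    av: EncodingDistribution,
    day1_fusion_fraction: float,
) -> EncodingDistribution:
    """Recalibrate: move A toward AV by the day-1 fusion fraction.

    A' lies on the segment [A center, AV center]; the covariance is untouched, so
    representational uncertainty is conserved through recalibration.  A zero
    fraction returns A unchanged (participants who never fused do not recalibrate).
    """
    f = day1_fusion_fraction
    if not 0 <= f <= 1:
        raise ValueError("fraction must be in [0, 1]")
    center = a.center + f * (av.center - a.center)
    return EncodingDistribution(center, a.variances, "A_shifted")


def shift_fraction_for_fusion_probability(
    a: EncodingDistribution,
    av: EncodingDistribution,
    space: RepresentationalSpace,
    target: float,
) -> float:
    """Shift fraction whose A' attains a given fusion probability (clamped to [0,1]).

    Monotone on [0, 1] whenever the AV center is no farther along the token line
    than the fusion token itself (always true for the default geometry); used by
    the cohort generator to relax a shift on the probability scale.
    """
    lo = posttest_fusion_probability(shift_auditory(a, av, 0.0), space)
    hi = posttest_fusion_probability(shift_auditory(a, av, 1.0), space)
    if target <= lo:
        return 0.0
    if target >= hi:
        return 1.0
    return float(
        brentq(
            lambda f: posttest_fusion_probability(shift_auditory(a, av, f), space)
            - target,
            0.0,
            1.0,
            xtol=1e-12,
        )
    )


# ---------------------------------------------------------------------------
# cohort-level prediction


def predict_cohort(
    trials: pd.DataFrame,
    stimuli: Mapping[str, StimulusSpec],
    config: ModelConfig | None = None,
    simulate: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-participant model fits and auditory-only post-test predictions.

    For each participant with coded exposure trials of the target McGurk stimulus:
    the day-1 fusion fraction (first exposure day, target stimulus only) sets the
    recalibration shift; ``p_common`` is inverted from the overall exposure fusion
    fraction; the predicted %FIR is the closed-form fusion mass of A', optionally
    accompanied by a Monte-Carlo estimate from ``config.n_sim_trials`` simulated
    trials.  The observed %FIR is the fusion percentage among 24-h post-test trials
    of the target's auditory-only component.  Participants with no day-1 exposure
    trials are skipped with a warning.

    Returns a frame with columns participant_id, day1_fusion_fraction, p_common,
    predicted_fir, observed_fir (percent scale) and, if ``simulate``,
    simulated_fir.
    """
    config = config or ModelConfig()
    target = stimuli[config.target_stimulus]
    space = config.space_for(target)
    a, v = config.encoders_for(space)
    pooled = pool_av(a, v)
    aud_ids = [
        s.stimulus_id for s in stimuli.values() if s.parent_id == target.stimulus_id
    ]
    if not aud_ids:
        raise ValueError(f"no auditory-only component registered for {target.stimulus_id}")
    aud_id = aud_ids[0]

    rows = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        expo = sub[(sub["phase"] == "exposure") & (sub["stimulus_id"] == target.stimulus_id)]
        if expo.empty:
            warnings.warn(f"participant {pid}: no exposure trials of {target.stimulus_id}; skipped")
            continue
        day1 = expo[expo["day_index"] == expo["day_index"].min()]
        if day1.empty:  # pragma: no cover - empty expo already skipped
            continue
        day1_frac = float((day1["coded_category"] == "Fusion").mean())
        overall_frac = float((expo["coded_category"] == "Fusion").mean())
        p_common = fit_p_common(overall_frac, a, v, space, config.integration)
        av = integrate_causal(a, pooled, p_common, config.integration)
        a_prime = shift_auditory(a, av, day1_frac)
        predicted = 100.0 * posttest_fusion_probability(a_prime, space)
        post = sub[(sub["phase"] == "posttest_24h") & (sub["stimulus_id"] == aud_id)]
        observed = (
            100.0 * float((post["coded_category"] == "Fusion").mean())
            if len(post)
            else np.nan
        )
        row = {
            "participant_id": pid,
            "day1_fusion_fraction": day1_frac,
            "p_common": p_common,
            "predicted_fir": predicted,
            "observed_fir": observed,
        }
        if simulate:
            if rng is None:
                raise ValueError("simulate=True needs an rng")
            percepts = simulate_posttest(a_prime, space, config.n_sim_trials, rng)
            row["simulated_fir"] = 100.0 * float(
                np.mean(percepts == space.fusion_token)
            )
        rows.append(row)
    return pd.DataFrame(rows)
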