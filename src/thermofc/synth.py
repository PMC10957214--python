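"""Synthetic multi-animal, multi-condition cohort generator with ground truth.

Emulates the statistical structure of awake functional-ultrasound ROI
recordings under thermal stimulation: latent connectivity states with
block-structured covariance (somatomotor-cingulate coupling, hypothalamus
anticorrelation), sticky Markov switching with condition-dependent occupancy
and per-animal random effects, slow polynomial drift, a shared global
component, band-limited dynamics (AR(1) smoothing), and sparse
high-amplitude motion-artifact bursts mirrored in a tissue-motion reference
trace.

The generator is the package's test bed: every downstream stage is validated
against the ground truth it records.  It does not attempt hemodynamic
convolution or ultrasound physics; signals are correlation-scaled latent
processes mapped to a positive CBV-like baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    CONDITION_LABELS,
    Acquisition,
    InvalidInputError,
    RoiSet,
    write_acquisition,
    write_manifest,
)

__all__ = [
    "StateTemplate",
    "SimulationConfig",
    "GroundTruth",
    "make_default_templates",
    "default_base_occupancy",
    "simulate_acquisition",
    "simulate_cohort",
    "simulate_state_blobs",
]


@dataclass(frozen=True)
class StateTemplate:
    """A latent brain state: a correlation-scaled covariance over the ROIs."""

    name: str
    covariance: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.covariance, dtype=float)
        if not np.allclose(c, c.T, atol=1e-10):
            raise InvalidInputError(f"template {self.name}: covariance not symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise InvalidInputError(f"template {self.name}: diagonal must be 1")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise InvalidInputError(f"template {self.name}: covariance not positive definite")
        object.__setattr__(self, "covariance", c)


def _corr_from_loadings(rows: list[np.ndarray]) -> np.ndarray:
    """Correlation matrix from factor loadings: L L' plus a diagonal filler.

    Guaranteed positive definite whenever every communality is < 1.
    """
    L = np.column_stack(rows)
    c = L @ L.T
    d = np.diag(c)
    if d.max() >= 1.0:
        raise InvalidInputError("factor loadings imply communality >= 1")
    return c + np.diag(1.0 - d)


def make_default_templates(roi: RoiSet | None = None) -> list[StateTemplate]:
    """The seven default latent connectivity states.

    State 1 is weakly connected (the dominant resting pattern).  States 3,
    5 and 7 share the somatomotor/cingulate-vs-hypothalamus dichotomy
    (strong positive SM-Cg block, anticorrelated hypothalamus) but differ in
    their internal structure: uniform coupling (3), S1-led with steep
    SM-vs-Cg gradient (5), and a lateralized hemisphere contrast (7).
    State 4 decouples the cingulate from everything else; states 2 and 6
    are intermediate, globally or somatomotor-dominantly coupled.
    """
    roi = roi or RoiSet()
    sm = roi.indices("somatomotor")
    cg = roi.indices("cingulate")
    hyp = roi.indices("hypothalamus")
    if not (sm and cg and hyp):
        raise InvalidInputError("RoiSet must populate all three network groups")
    n = roi.n
    z = np.zeros(n)

    def load(pairs: list[tuple[list[int], float]]) -> np.ndarray:
        v = z.copy()
        for idx, val in pairs:
            v[idx] = val
        return v

    # Lateral splits by canonical order: left hemisphere first (indices
    # below n/2 within the cortical block; HyThL is the first hypothalamic ROI).
    smcg = sorted(sm + cg)
    cort_left = [i for i in smcg if i < n // 2]
    cort_right = [i for i in smcg if i >= n // 2]
    left = cort_left + hyp[:1]
    right = cort_right + hyp[1:]
    s1 = [sm[0], sm[-1]]
    m2 = [sm[2], sm[3]]

    templates = [
        StateTemplate(
            "weak",
            _corr_from_loadings([load([(list(range(n)), 0.25)])]),
            "weakly correlated resting pattern, all |r| <= 0.15",
        ),
        StateTemplate(
            "limbic-coupled",
            _corr_from_loadings([load([(cg + hyp, 0.85), (sm, -0.35)])]),
            "strong cingulate-hypothalamic coupling, somatomotor suppressed",
        ),
        StateTemplate(
            "dichotomy-uniform",
            _corr_from_loadings([
                load([(sm + cg, 0.82), (hyp, -0.50)]),
                load([(hyp, 0.62)]),
            ]),
            "uniform SM-Cg coupling, hypothalamus anticorrelated",
        ),
        StateTemplate(
            "cingulate-decoupled",
            _corr_from_loadings([
                load([(sm, 0.66), (hyp, -0.76)]),
                load([(hyp, 0.50)]),
                load([(cg, 0.72)]),
            ]),
            "SM-hypothalamus dichotomy with the cingulate disconnected "
            "from all other areas",
        ),
        StateTemplate(
            "dichotomy-s1-led",
            _corr_from_loadings([
                load([(sm, 0.90), (cg, 0.50), (hyp, -0.36)]),
                load([(cg, 0.62), (hyp, -0.35)]),
                load([(hyp, 0.62)]),
                load([(s1, 0.25), (m2, -0.25)]),
            ]),
            "SM-dominated dichotomy with steep SM-vs-Cg gradient",
        ),
        StateTemplate(
            "lateralized",
            _corr_from_loadings([load([(left, 0.82), (right, -0.30)])]),
            "left-hemisphere coupling with mild contralateral anticorrelation",
        ),
        StateTemplate(
            "dichotomy-lateral",
            _corr_from_loadings([
                load([(sm + cg, 0.80), (hyp, -0.46)]),
                load([(cort_left, 0.45), (cort_right, -0.45)]),
                load([(hyp, 0.60)]),
            ]),
            "dichotomy with a left-right hemisphere contrast",
        ),
    ]
    return templates


def default_base_occupancy() -> dict[str, np.ndarray]:
    """Per-condition stationary occupancy over the seven default states.

    The weak state dominates everywhere and peaks at thermoneutral 25C; the
    dichotomy states (3, 5, 7) are elevated during cool fast-down ramps; the
    cingulate-decoupled state (4) is elevated during sustained cold (15C).
    Warm conditions track the neutral profile.
    """
    warm = np.array([0.60, 0.08, 0.06, 0.05, 0.07, 0.08, 0.06])
    occ = {
        "25C": np.array([0.62, 0.08, 0.06, 0.04, 0.06, 0.08, 0.06]),
        "35C": np.array([0.58, 0.09, 0.06, 0.05, 0.07, 0.09, 0.06]),
        "15C": np.array([0.46, 0.08, 0.07, 0.18, 0.07, 0.07, 0.07]),
        "CFD": np.array([0.40, 0.06, 0.13, 0.05, 0.13, 0.06, 0.17]),
        "CFU": np.array([0.50, 0.06, 0.10, 0.05, 0.10, 0.06, 0.13]),
        "CSD": np.array([0.52, 0.07, 0.08, 0.08, 0.08, 0.07, 0.10]),
        "CSU": np.array([0.52, 0.07, 0.09, 0.06, 0.09, 0.07, 0.10]),
        "WFU": warm.copy(),
        "WFD": warm.copy(),
        "WSU": warm.copy(),
        "WSD": warm.copy(),
    }
    return occ


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator.

    Defaults define the reference study conditions used by the package's
    benchmarks: 2.5 Hz sampling, 3000-frame (20 min) acquisitions, sticky
    state switching (expected dwell 20 frames = 8 s), band-limited dynamics,
    and sparse 10x motion bursts.
    """

    roi: RoiSet = field(default_factory=RoiSet)
    templates: list[StateTemplate] | None = None
    transition_stickiness: float = 0.95
    base_occupancy: dict[str, np.ndarray] | None = None
    animal_sd: float = 0.3
    fs: float = 2.5
    frames_per_acq: int = 3000
    ar_coeff: float = 0.9
    drift_amplitude: float = 0.5
    global_amplitude: float = 0.5
    artifact_rate: float = 3.0  # expected bursts per 1000 frames
    artifact_gain: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.templates is None:
            self.templates = make_default_templates(self.roi)
        if self.base_occupancy is None:
            self.base_occupancy = default_base_occupancy()
        if not 0 <= self.transition_stickiness < 1:
            raise InvalidInputError("transition_stickiness must be in [0, 1)")
        if abs(self.ar_coeff) >= 1:
            raise InvalidInputError("|ar_coeff| must be < 1")
        k = len(self.templates)
        for cond, occ in self.base_occupancy.items():
            occ = np.asarray(occ, dtype=float)
            if occ.shape != (k,) or np.any(occ < 0) or abs(occ.sum() - 1) > 1e-9:
                raise InvalidInputError(
                    f"occupancy for {cond} must be a length-{k} simplex vector"
                )
            self.base_occupancy[cond] = occ

    @property
    def n_states(self) -> int:
        return len(self.templates)


@dataclass
class GroundTruth:
    """Per-acquisition generator truth for validating the pipeline."""

    state_sequence: np.ndarray  # (T_raw,) int state labels
    artifact_mask: np.ndarray  # (T_raw,) bool, True = artifact frame
    occupancy_realized: np.ndarray  # (K,) state proportions
    animal_effects: np.ndarray  # (K,) per-animal logit offsets

    def __post_init__(self) -> None:
        if self.state_sequence.shape != self.artifact_mask.shape:
            raise InvalidInputError("state_sequence and artifact_mask lengths differ")
        if abs(self.occupancy_realized.sum() - 1) > 1e-9:
            raise InvalidInputError("realized occupancy must sum to 1")


def _softmax_occupancy(base: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    logits = np.log(np.clip(base, 1e-12, None)) + offsets
    e = np.exp(logits - logits.max())
    return e / e.sum()


def _sample_markov_chain(rng: np.random.Generator, pi: np.ndarray,
                         stickiness: float, t: int) -> np.ndarray:
    """Sticky chain with P = s*I + (1-s)*1 pi'; stationary distribution pi."""
    states = np.empty(t, dtype=np.int64)
    k = len(pi)
    states[0] = rng.choice(k, p=pi)
    stay = rng.random(t)
    jumps = rng.choice(k, size=t, p=pi)
    for i in range(1, t):
        states[i] = states[i - 1] if stay[i] < stickiness else jumps[i]
    return states

CBV_BASELINE = 100.0
CBV_SCALE = 5.0
MOTION_BASELINE = 1.0
MOTION_SCALE = 0.2
BURST_LEN_MAX = 10


def simulate_acquisition(
    config: SimulationConfig,
    animal_id: str,
    condition: str,
    seed: int,
    *,
    acquisition_id: str = "",
    animal_offsets: np.ndarray | None = None,
) -> tuple[Acquisition, GroundTruth]:
    """Simulate one imaging session.

    The latent process per frame t is ``x_t = a x_{t-1} + sqrt(1-a^2) e_t``
    with ``e_t ~ N(0, Sigma_{state_t})``, so each ROI keeps unit marginal
    variance while the spectrum is band-limited.  Cubic drift, a shared
    AR(1) global component, and multiplicative artifact bursts (mirrored as
    spikes in ``motion_ref``) are added on top, and the sum is mapped to a
    positive CBV-like scale.
    """
    if condition not in config.base_occupancy:
        raise InvalidInputError(f"no base occupancy defined for condition {condition!r}")
    rng = np.random.default_rng(seed)
    k = config.n_states
    n = config.roi.n
    t = config.frames_per_acq

    offsets = np.zeros(k) if animal_offsets is None else np.asarray(animal_offsets, float)
    pi = _softmax_occupancy(config.base_occupancy[condition], offsets)
    states = _sample_markov_chain(rng, pi, config.transition_stickiness, t)

    chols = [np.linalg.cholesky(tpl.covariance) for tpl in config.templates]
    white = rng.standard_normal((t, n))
    innov = np.empty((t, n))
    for s in range(k):
        sel = states == s
        if sel.any():
            innov[sel] = white[sel] @ chols[s].T

    a = config.ar_coeff
    x = np.empty((t, n))
    x[0] = innov[0]
    scale = np.sqrt(1.0 - a * a)
    for i in range(1, t):
        x[i] = a * x[i - 1] + scale * innov[i]
    x = x.T  # (n, t)

    if config.drift_amplitude > 0 and t > 3:
        u = np.linspace(-1.0, 1.0, t)
        basis = np.vstack([u, u**2, u**3])
        coeff = rng.standard_normal((n, 3))
        drift = coeff @ basis
        sd = drift.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = x + config.drift_amplitude * drift / sd

    if config.global_amplitude > 0:
        g = np.empty(t)
        gw = rng.standard_normal(t)
        g[0] = gw[0]
        for i in range(1, t):
            g[i] = a * g[i - 1] + scale * gw[i]
        x = x + config.global_amplitude * g[np.newaxis, :]

    # tissue-motion energy aggregates many pixels, so its quiet-state
    # distribution is concentrated and near-Gaussian
    motion = np.clip(MOTION_BASELINE + MOTION_SCALE * rng.standard_normal(t), 0.05, None)
    artifact = np.zeros(t, dtype=bool)
    if config.artifact_rate > 0:
        n_bursts = rng.poisson(config.artifact_rate * t / 1000.0)
        if n_bursts > 0:
            starts = rng.integers(0, t, size=n_bursts)
            lengths = rng.integers(1, BURST_LEN_MAX + 1, size=n_bursts)
            for s0, ln in zip(starts, lengths):
                artifact[s0:min(s0 + ln, t)] = True
        x[:, artifact] *= config.artifact_gain
        motion[artifact] *= config.artifact_gain

    signals = CBV_BASELINE + CBV_SCALE * x
    occupancy = np.bincount(states, minlength=k).astype(float) / t

    acq = Acquisition(
        acquisition_id=acquisition_id or f"{animal_id}_{condition}_{seed}",
        animal_id=animal_id,
        condition=condition,
        fs=config.fs,
        signals=signals,
        roi=config.roi,
        motion_ref=motion,
    )
    truth = GroundTruth(
        state_sequence=states,
        artifact_mask=artifact,
        occupancy_realized=occupancy,
        animal_effects=offsets,
    )
    return acq, truth


def simulate_state_blobs(templates: list[StateTemplate], n_per_state: int,
                         noise_sd: float = 0.1, seed: int = 0,
                         with_diagonal: bool = True
                         ) -> tuple[np.ndarray, np.ndarray]:
    """High-separation cofluctuation patterns: template vectors plus jitter.

    Emulates the regime where each observation is a dwell-averaged
    cofluctuation pattern rather than a single noisy frame: the vectorized
    template plus isotropic Gaussian jitter of scale ``noise_sd`` (a
    dwell-median of m frames has per-coordinate scatter of roughly
    1.25/sqrt(m), so the 0.1 default corresponds to long dwells).  Used for
    validating cluster-number selection, where well-separated groups are the
    relevant regime.  Returns (X, labels).
    """
    rng = np.random.default_rng(seed)
    n = templates[0].covariance.shape[0]
    rows, cols = np.triu_indices(n, k=0 if with_diagonal else 1)
    frames = []
    labels = []
    for s, tpl in enumerate(templates):
        v = tpl.covariance[rows, cols]
        frames.append(v + noise_sd * rng.standard_normal((n_per_state, v.size)))
        labels.append(np.full(n_per_state, s))
    return np.vstack(frames), np.concatenate(labels)


def _rle(labels: np.ndarray) -> list[list[int]]:
    """Run-length encode an integer label stream as [value, length] pairs."""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return [[int(labels[s]), int(e - s)] for s, e in zip(starts, ends)]


def simulate_cohort(
    config: SimulationConfig,
    n_animals: int,
    acquisitions_per_condition: int,
    conditions: list[str],
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[Acquisition, GroundTruth]], "pd.DataFrame"]:
    """Simulate a cohort; optionally write acquisition files plus a manifest.

    Per-animal occupancy logit offsets are drawn once per animal and shared
    across all that animal's sessions, matching the random-intercept
    structure the downstream mixed models assume.  When ``out_dir`` is set,
    acquisition files, manifest.csv and ground_truth.json (state sequences
    run-length encoded) are written there.
    """
    import pandas as pd

    if n_animals < 1:
        raise InvalidInputError("n_animals must be >= 1")
    for cond in conditions:
        if cond not in CONDITION_LABELS:
            raise InvalidInputError(f"unknown condition {cond!r}")
    master = np.random.default_rng(seed)
    k = config.n_states
    animal_ids = [f"m{idx + 1:02d}" for idx in range(n_animals)]
    offsets = {
        aid: config.animal_sd * master.standard_normal(k) for aid in animal_ids
    }

    results: list[tuple[Acquisition, GroundTruth]] = []
    rows = []
    for aid in animal_ids:
        for cond in conditions:
            for rep in range(acquisitions_per_condition):
                acq_seed = int(master.integers(0, 2**31 - 1))
                acq_id = f"{aid}_{cond}_s{rep + 1}"
                acq, truth = simulate_acquisition(
                    config, aid, cond, acq_seed,
                    acquisition_id=acq_id, animal_offsets=offsets[aid],
                )
                results.append((acq, truth))
                rows.append({
                    "acquisition_id": acq_id,
                    "animal_id": aid,
                    "condition": cond,
                    "fs_hz": config.fs,
                    "path": f"{acq_id}.csv",
                })
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            for (acq, _), row in zip(results, rows):
                write_acquisition(out / row["path"], acq)
            write_manifest(out / "manifest.csv", rows)
            gt = {
                row["acquisition_id"]: {
                    "state_sequence_rle": _rle(truth.state_sequence),
                    "artifact_frames": np.flatnonzero(truth.artifact_mask).tolist(),
                    "occupancy_realized": truth.occupancy_realized.tolist(),
                    "animal_effects": truth.animal_effects.tolist(),
                }
                for (_, truth), row in zip(results, rows)
            }
            with open(out / "ground_truth.json", "w") as fh:
                json.dump(gt, fh)
        except OSError as exc:
            raise OSError(f"failed writing cohort to {out}: {exc}") from exc

    return results, manifest
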