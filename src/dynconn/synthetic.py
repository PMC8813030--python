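"""Synthetic state-switching cohort generator.

Emulates the statistical structure the downstream analysis assumes: each
subject's component time courses are draws from a hidden-Markov switching
multivariate Gaussian with two recurring covariance "states" — one with
elevated within-network correlations, one with elevated between-network
correlations — plus independent observation noise.  Groups differ in their
state transition matrices (hence state occupancy) and in multiplicative
edge-block effects on the covariance (cortical-cortical scaled down,
subcortical-cortical scaled up for the RTLE-like group), mirroring the
direction of effects the analysis is designed to detect.

A cognitive screening sub-item (MoCA-style) is generated as a decreasing
linear function of the subject's realized between-network-state occupancy,
so the partial-correlation stage has a recoverable negative association.

Everything is deterministic given the cohort seed: per-subject seeds are
spawned from the master seed via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import TimecourseSet

__all__ = [
    "NETWORKS",
    "StateSpec",
    "CohortSpec",
    "default_partition",
    "build_state_covariances",
    "repair_positive_definite",
    "stationary_distribution",
    "simulate_subject",
    "simulate_cohort",
    "truth_to_json",
    "truth_from_json",
]

#: Canonical network order used everywhere downstream.
NETWORKS = ("SCN", "AUD", "SMN", "VIS", "CCN", "DMN", "CBN")

#: Components per network for the default 43-component partition.
_DEFAULT_SIZES = {
    "SCN": 5, "AUD": 2, "SMN": 6, "VIS": 10, "CCN": 7, "DMN": 8, "CBN": 5,
}

#: Eigenvalue floor used by positive-definiteness repair.
EIG_FLOOR = 1e-4

#: MoCA-style sub-items and their maximum points (screening-instrument scale).
MOCA_ITEMS = {
    "executive": 5,
    "language": 3,
    "orientation": 6,
    "calculation": 3,
    "conceptual_thinking": 3,
    "memory": 5,
    "visuoperception": 3,
    "naming": 3,
    "attention": 2,
}


def default_partition(n_components: int = 43) -> np.ndarray:
    """Network label per component, in canonical network order.

    For the default 43 components uses fixed per-network counts
    (SCN 5, AUD 2, SMN 6, VIS 10, CCN 7, DMN 8, CBN 5); for other sizes the
    counts are scaled proportionally (largest-remainder rounding).
    """
    if n_components == 43:
        sizes = dict(_DEFAULT_SIZES)
    else:
        raw = {k: v * n_components / 43 for k, v in _DEFAULT_SIZES.items()}
        sizes = {k: int(np.floor(v)) for k, v in raw.items()}
        rem = n_components - sum(sizes.values())
        order = sorted(raw, key=lambda k: raw[k] - sizes[k], reverse=True)
        for k in order[:rem]:
            sizes[k] += 1
        for k in NETWORKS:  # every network keeps at least one component
            while sizes[k] == 0:
                donor = max(sizes, key=sizes.get)
                sizes[donor] -= 1
                sizes[k] += 1
    labels = []
    for net in NETWORKS:
        labels.extend([net] * sizes[net])
    return np.array(labels[:n_components])


@dataclass
class StateSpec:
    """One recurring covariance state.

    ``covariance`` is a correlation-scale positive-definite matrix with unit
    diagonal; ``label`` names the archetype it realizes.
    """

    state_id: int
    covariance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if not np.allclose(cov, cov.T):
            raise ValueError("state covariance must be symmetric")
        ev = np.linalg.eigvalsh(cov)
        if ev.min() <= 0:
            raise ValueError("state covariance must be positive definite")
        if not np.allclose(np.diag(cov), 1.0, atol=1e-8):
            raise ValueError("state covariance must have unit diagonal")
        self.covariance = cov


def repair_positive_definite(
    mat: np.ndarray, floor: float = EIG_FLOOR, max_defect: float = 0.1
) -> np.ndarray:
    """Symmetrize, clamp eigenvalues at ``floor``, rescale to unit diagonal.

    Raises if the matrix is indefinite beyond ``max_defect`` (most negative
    eigenvalue below ``-max_defect``): such inputs cannot be repaired without
    materially changing the requested structure, so failure is explicit
    rather than a silent large clamp.
    """
    mat = 0.5 * (mat + mat.T)
    w, v = np.linalg.eigh(mat)
    if w.min() < -max_defect:
        raise ValueError(
            f"matrix is not repairable: min eigenvalue {w.min():.4f} < -{max_defect}"
        )
    w = np.clip(w, floor, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    return out


def build_state_covariances(
    partition: np.ndarray,
    within_strength: float = 0.45,
    between_strength: float = 0.15,
    jitter_sd: float = 0.02,
    seed: int | None = None,
) -> list[StateSpec]:
    """Construct the two archetypal state covariances.

    State I ("within-network dominant") places ``within_strength`` on
    same-network off-diagonal entries and ``between_strength`` elsewhere.
    State II ("between-network dominant") is a global-coupling state with
    every off-diagonal entry at the midpoint of the two strengths: its
    between-network couplings are elevated relative to state I and its
    within-network coherence reduced.  (A matrix whose between-network
    entries all exceed its within-network entries is far from positive
    definite at realistic sizes, so between-dominance is expressed
    relative to state I, not within state II itself.)  Off-diagonal
    Gaussian jitter is added symmetrically, then each matrix is repaired to
    positive definiteness (eigenvalue floor ``EIG_FLOOR``, rescale to unit
    diagonal).
    """
    for name, s in (("within_strength", within_strength),
                    ("between_strength", between_strength)):
        if not -1.0 < s < 1.0:
            raise ValueError(f"{name} must be in (-1, 1), got {s}")
    partition = np.asarray(partition)
    c = partition.size
    same = partition[:, None] == partition[None, :]
    rng = np.random.default_rng(seed)

    specs = []
    mid = 0.5 * (within_strength + between_strength)
    layouts = [
        (within_strength, between_strength, "within-network dominant"),
        (mid, mid, "between-network dominant"),
    ]
    for state_id, (w_in, w_out, label) in enumerate(layouts):
        mat = np.where(same, w_in, w_out).astype(float)
        np.fill_diagonal(mat, 1.0)
        if jitter_sd > 0:
            noise = rng.normal(0.0, jitter_sd, size=(c, c))
            noise = 0.5 * (noise + noise.T)
            np.fill_diagonal(noise, 0.0)
            mat = mat + noise
        mat = repair_positive_definite(mat)
        specs.append(StateSpec(state_id=state_id, covariance=mat, label=label))
    return specs


# Group-specific two-state transition matrices (row-stochastic).  HC and LTLE
# share a state-I-dominant chain (stationary state-II occupancy 0.294); the
# RTLE-like chain spends more time in the between-network state (0.556).
_DEFAULT_TRANSITIONS = {
    "HC": [[0.95, 0.05], [0.12, 0.88]],
    "LTLE": [[0.95, 0.05], [0.12, 0.88]],
    "RTLE": [[0.90, 0.10], [0.08, 0.92]],
}

# Multiplicative covariance-block effects: cortical-cortical (both components
# outside SCN) and subcortical-cortical (exactly one component in SCN).
_DEFAULT_GROUP_EFFECTS = {
    "HC": {"cortical_cortical": 1.0, "subcortical_cortical": 1.0},
    "LTLE": {"cortical_cortical": 1.0, "subcortical_cortical": 1.0},
    "RTLE": {"cortical_cortical": 0.85, "subcortical_cortical": 1.3},
}


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    Defaults reproduce the study design the pipeline targets: three groups
    (HC 37, LTLE 22, RTLE 31), 43 components in seven networks, 215 retained
    TRs at TR = 2 s, two recurring covariance states.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"HC": 37, "LTLE": 22, "RTLE": 31}
    )
    n_components: int = 43
    n_timepoints: int = 215
    tr_seconds: float = 2.0
    transition_matrices: Mapping[str, list] = field(
        default_factory=lambda: {k: [list(r) for r in v]
                                 for k, v in _DEFAULT_TRANSITIONS.items()}
    )
    partition: np.ndarray | None = None
    group_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in _DEFAULT_GROUP_EFFECTS.items()}
    )
    within_strength: float = 0.45
    between_strength: float = 0.15
    jitter_sd: float = 0.02
    noise_sd: float = 0.3
    moca_linked_item: str = "conceptual_thinking"
    moca_slope: float = 3.0
    moca_noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.partition is None:
            self.partition = default_partition(self.n_components)
        self.partition = np.asarray(self.partition)
        if self.partition.size != self.n_components:
            raise ValueError("partition length must equal n_components")
        for g, n in self.n_per_group.items():
            if n < 0:
                raise ValueError(f"negative count for group {g}")
            if n > 0 and g not in self.transition_matrices:
                raise ValueError(f"no transition matrix for group {g}")
        for g, p in self.transition_matrices.items():
            p = np.asarray(p, dtype=float)
            if p.ndim != 2 or p.shape[0] != p.shape[1]:
                raise ValueError(f"transition matrix for {g} must be square")
            if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0):
                raise ValueError(f"transition matrix for {g} is not row-stochastic")
        if self.moca_linked_item not in MOCA_ITEMS:
            raise ValueError(f"unknown MoCA item {self.moca_linked_item!r}")

    @property
    def groups(self) -> list[str]:
        return [g for g in ("HC", "LTLE", "RTLE") if self.n_per_group.get(g, 0) > 0] + [
            g for g in self.n_per_group
            if g not in ("HC", "LTLE", "RTLE") and self.n_per_group[g] > 0
        ]


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    p = np.asarray(transition, dtype=float)
    w, v = np.linalg.eig(p.T)
    idx = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def _apply_group_effects(
    cov: np.ndarray, partition: np.ndarray, effects: Mapping[str, float]
) -> np.ndarray:
    """Scale covariance edge blocks by group multipliers, then re-repair.

    Multipliers act on the correlation-scale covariance (not on time courses)
    so injected effect sizes are interpretable in correlation units.  The
    subcortical-subcortical block is co-scaled with the subcortical-cortical
    multiplier: raising cross-block correlations without strengthening the
    subcortical factor itself is geometrically unrealizable (the implied
    matrix is far from any correlation matrix), and co-scaling keeps the
    positive-definiteness defect small enough that eigenvalue-clamping
    repair preserves most of the requested effect.  Scaled entries are
    capped at |0.9| and the result repaired (floor ``EIG_FLOOR``, defect
    tolerance 0.25).
    """
    m_cc = float(effects.get("cortical_cortical", 1.0))
    m_sc = float(effects.get("subcortical_cortical", 1.0))
    if m_cc == 1.0 and m_sc == 1.0:
        return cov
    sub = partition == "SCN"
    cortical = ~sub
    offdiag = ~np.eye(cov.shape[0], dtype=bool)
    out = cov.copy()
    out[np.outer(cortical, cortical) & offdiag] *= m_cc
    out[np.outer(sub, cortical) | np.outer(cortical, sub)] *= m_sc
    out[np.outer(sub, sub) & offdiag] *= m_sc
    out = np.clip(out, -0.9, 0.9)
    np.fill_diagonal(out, 1.0)
    return repair_positive_definite(out, max_defect=0.25)


def simulate_subject(
    spec: CohortSpec,
    group: str,
    states: list[StateSpec],
    seed,
    subject_id: str = "sub",
    start_state: int | None = None,
) -> tuple[TimecourseSet, np.ndarray]:
    """Simulate one subject's time courses plus the true state sequence.

    The hidden state follows the group's Markov chain started from its
    stationary distribution (or ``start_state`` when given); each TR's
    observation is multivariate normal with the active state's
    (group-effect-adjusted) covariance plus independent N(0, noise_sd^2)
    noise.
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(spec.transition_matrices[group], dtype=float)
    if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0):
        raise ValueError("transition matrix is not row-stochastic")
    k = p.shape[0]
    if len(states) != k:
        raise ValueError("number of states must match transition matrix order")
    t, c = spec.n_timepoints, spec.n_components
    for s in states:
        if s.covariance.shape[0] != c:
            raise ValueError("state covariance size must equal n_components")

    effects = spec.group_effects.get(group, {})
    chols = [
        np.linalg.cholesky(
            _apply_group_effects(s.covariance, spec.partition, effects)
        )
        for s in states
    ]

    pi = stationary_distribution(p)
    seq = np.empty(t, dtype=int)
    seq[0] = rng.choice(k, p=pi) if start_state is None else start_state
    u = rng.random(t - 1)
    cum = np.cumsum(p, axis=1)
    for i in range(1, t):
        seq[i] = np.searchsorted(cum[seq[i - 1]], u[i - 1], side="right")

    innov = rng.standard_normal((t, c))
    data = np.empty((t, c))
    for s in range(k):
        mask = seq == s
        if mask.any():
            data[mask] = innov[mask] @ chols[s].T
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal((t, c))

    ts = TimecourseSet(
        subject_id=subject_id, data=data, tr_seconds=spec.tr_seconds
    )
    return ts, seq


def _truncated_normal(rng, mean, sd, lo, hi):
    x = rng.normal(mean, sd)
    while not lo <= x <= hi:
        x = rng.normal(mean, sd)
    return x


def _simulate_meta(rng, subject_id, group, t, occupancy_between, spec):
    """Metadata covariates and MoCA scores for one subject.

    Covariate distributions are plumbing loosely matched to a young-adult
    cohort: age ~ N(30, 8) truncated to [18, 60], education ~ N(13, 2.5)
    truncated to [6, 20], per-volume FD ~ |N(0.08, 0.04)|.  The configured
    MoCA sub-item decreases linearly in the subject's realized occupancy of
    the between-network state (slope ``moca_slope`` points per unit
    occupancy) with Gaussian noise, rounded and clipped to instrument range.
    """
    age = _truncated_normal(rng, 30.0, 8.0, 18.0, 60.0)
    sex = "M" if rng.random() < 0.45 else "F"
    education = _truncated_normal(rng, 13.0, 2.5, 6.0, 20.0)
    fd_trace = np.abs(rng.normal(0.08, 0.04, size=t))
    moca = {}
    for item, max_pts in MOCA_ITEMS.items():
        if item == spec.moca_linked_item:
            raw = (
                max_pts
                - spec.moca_slope * occupancy_between
                + rng.normal(0.0, spec.moca_noise_sd)
            )
            moca[item] = int(np.clip(np.round(raw), 0, max_pts))
        else:
            moca[item] = int(rng.binomial(max_pts, 0.85))
    meta = {
        "subject_id": subject_id,
        "group": group,
        "age": round(age, 1),
        "sex": sex,
        "education": round(education, 1),
        "mean_fd": float(np.mean(fd_trace)),
        "moca_total": int(sum(moca.values())),
    }
    meta.update({f"moca_{k}": v for k, v in moca.items()})
    return meta, fd_trace


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[list[TimecourseSet], pd.DataFrame, dict]:
    """Simulate a full cohort: time courses, metadata table, truth record.

    The truth record stores every latent quantity needed by recovery tests:
    state covariances, per-group transition matrices and stationary
    distributions, per-subject true state sequences and realized occupancy,
    and per-subject seeds.  It round-trips through
    :func:`truth_to_json` / :func:`truth_from_json` unchanged.
    """
    master = np.random.SeedSequence(spec.seed)
    ss_states, ss_subjects = master.spawn(2)
    states = build_state_covariances(
        spec.partition,
        within_strength=spec.within_strength,
        between_strength=spec.between_strength,
        jitter_sd=spec.jitter_sd,
        seed=ss_states,
    )

    n_total = sum(spec.n_per_group.get(g, 0) for g in spec.groups)
    child_seeds = ss_subjects.spawn(n_total)

    timecourses: list[TimecourseSet] = []
    meta_rows = []
    truth: dict = {
        "spec": {
            "n_per_group": dict(spec.n_per_group),
            "n_components": spec.n_components,
            "n_timepoints": spec.n_timepoints,
            "tr_seconds": spec.tr_seconds,
            "noise_sd": spec.noise_sd,
            "within_strength": spec.within_strength,
            "between_strength": spec.between_strength,
            "seed": spec.seed,
        },
        "partition": spec.partition.tolist(),
        "state_covariances": [s.covariance.tolist() for s in states],
        "state_labels": [s.label for s in states],
        "transition_matrices": {
            g: np.asarray(m, dtype=float).tolist()
            for g, m in spec.transition_matrices.items()
        },
        "stationary": {
            g: stationary_distribution(np.asarray(m)).tolist()
            for g, m in spec.transition_matrices.items()
        },
        "subjects": {},
    }

    idx = 0
    for group in spec.groups:
        for j in range(spec.n_per_group[group]):
            subject_id = f"sub-{group}{j + 1:03d}"
            child = child_seeds[idx]
            idx += 1
            ts, seq = simulate_subject(
                spec, group, states, seed=child, subject_id=subject_id
            )
            k = len(states)
            occupancy = np.bincount(seq, minlength=k) / seq.size
            meta_rng = np.random.default_rng(child.spawn(1)[0])
            meta, fd_trace = _simulate_meta(
                meta_rng, subject_id, group, spec.n_timepoints,
                occupancy[-1], spec,
            )
            timecourses.append(ts)
            meta_rows.append(meta)
            truth["subjects"][subject_id] = {
                "group": group,
                "state_sequence": seq.tolist(),
                "occupancy": occupancy.tolist(),
                "fd_trace": np.round(fd_trace, 6).tolist(),
                "seed_entropy": int(child.entropy),
                "seed_spawn_key": [int(x) for x in child.spawn_key],
            }

    metadata = pd.DataFrame(meta_rows)
    return timecourses, metadata, truth


def truth_to_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def truth_from_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
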