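"""Synthetic multi-subject resting-state cohort generator.

Produces every input the analysis chain consumes — rigid-body motion
traces, ROI time series with a planted tree-structured correlation
topology, tissue-mean signals, and pre/post clinical (CAPS) scores with a
planted responder effect — so the pipeline can run end-to-end without
real imaging data.

The ROI signal model is a latent-component construction: a unit-variance
latent source at the tree root is propagated along planted tree edges
with per-edge attenuation ``a`` (``z_child = a * z_parent +
sqrt(1 - a^2) * eps``), then observed with additive white noise of
standard deviation ``sigma``.  The population correlation between ROIs at
tree distance ``d`` is ``a^d / (1 + sigma^2)``, strictly decreasing in
``d``, so the planted tree is the unique maximum-weight spanning tree of
the population correlation matrix.  Latent sources (and the propagation
innovations) are unit-variance AR(1) processes rather than white noise,
concentrating their power at low frequencies the way BOLD fluctuations
do; the correlation formula is spectrum-independent, but band-pass
filtering downstream then preserves the planted structure instead of
erasing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from mstconnect.connectome import _UnionFind
from mstconnect.preprocess import MotionTrace, RoiTimeSeries

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "ReductionLaw",
    "random_spanning_tree",
    "hub_spanning_tree",
    "validate_spanning_tree",
    "simulate_motion",
    "simulate_roi_timeseries",
    "simulate_caps",
    "simulate_cohort",
    "write_cohort",
]

# Innovation scales at motion scale 1.0: chosen so a typical subject's FD
# sits well below the 0.2 mm censoring threshold with occasional spikes
# crossing it (translations in mm, rotations in radians; 80 mm head radius
# maps 3.75e-4 rad to ~0.03 mm of surface displacement).
_TRANS_INNOV_SD = 0.03
_ROT_INNOV_SD = 3.75e-4
_AR_RHO = 0.98
# AR(1) coefficient of the unit-variance latent BOLD-like sources; at
# TR = 1.6 s this puts most signal power below ~0.1 Hz
_LATENT_AR_RHO = 0.85


def _unit_ar1(rng: np.random.Generator, shape, rho: float = _LATENT_AR_RHO) -> np.ndarray:
    """Stationary unit-variance AR(1) noise along the last axis."""
    from scipy.signal import lfilter

    innov = rng.normal(size=shape)
    w = innov * np.sqrt(1.0 - rho**2)
    w[..., 0] = innov[..., 0]  # stationary start: x_0 ~ N(0, 1)
    return lfilter([1.0], [1.0, -rho], w, axis=-1)


def validate_spanning_tree(edges, n_nodes: int) -> list[tuple[int, int]]:
    """Check an edge list is a spanning tree over ``n_nodes`` (union-find)."""
    edges = [(int(i), int(j)) for i, j in edges]
    if len(edges) != n_nodes - 1:
        raise ValueError(
            f"a spanning tree on {n_nodes} nodes needs {n_nodes - 1} edges, got {len(edges)}"
        )
    uf = _UnionFind(n_nodes)
    for i, j in edges:
        if not (0 <= i < n_nodes and 0 <= j < n_nodes) or i == j:
            raise ValueError(f"invalid edge ({i}, {j})")
        if not uf.union(i, j):
            raise ValueError(f"edge ({i}, {j}) creates a cycle")
    if uf.n_components != 1:
        raise ValueError("edge list does not connect all nodes")
    return edges


def random_spanning_tree(n_nodes: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniform random labelled spanning tree via a random Pruefer sequence."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if n_nodes == 2:
        return [(0, 1)]
    prufer = rng.integers(0, n_nodes, size=n_nodes - 2)
    degree = np.ones(n_nodes, dtype=int)
    for v in prufer:
        degree[v] += 1
    edges = []
    import heapq

    leaves = [v for v in range(n_nodes) if degree[v] == 1]
    heapq.heapify(leaves)
    for v in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((min(leaf, int(v)), max(leaf, int(v))))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, int(v))
    u, v = heapq.heappop(leaves), heapq.heappop(leaves)
    edges.append((min(u, v), max(u, v)))
    return edges


def hub_spanning_tree(
    n_nodes: int,
    hubs: list[int],
    hub_attachment: float = 0.5,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[tuple[int, int]]:
    """Spanning tree with planted hub nodes of elevated degree/centrality.

    Nodes are attached sequentially; each new node connects to one of the
    ``hubs`` with probability ``hub_attachment`` (uniform over hubs) and
    otherwise to a uniformly random already-attached node.
    ``hub_attachment = 0`` reduces to a random-attachment tree.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    hubs = [int(h) for h in hubs]
    if any(not 0 <= h < n_nodes for h in hubs):
        raise ValueError("hub indices out of range")
    order = [hubs[0]] if hubs else [0]
    remaining = [v for v in range(n_nodes) if v != order[0]]
    # attach remaining hubs first so they exist early in the tree
    remaining.sort(key=lambda v: (v not in hubs, v))
    edges = []
    attached = [order[0]]
    for v in remaining:
        if hubs and rng.random() < hub_attachment:
            candidates = [h for h in hubs if h in attached and h != v]
        else:
            candidates = []
        target = (
            candidates[rng.integers(len(candidates))]
            if candidates
            else attached[rng.integers(len(attached))]
        )
        edges.append((min(v, target), max(v, target)))
        attached.append(v)
    return edges


@dataclass
class ReductionLaw:
    """Truncated-normal law for the fractional CAPS reduction."""

    mean: float
    sd: float
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator) -> float:
        for _ in range(10000):
            x = rng.normal(self.mean, self.sd)
            if self.lo <= x <= self.hi:
                return float(x)
        raise RuntimeError("truncated-normal rejection sampling failed")


#: Responder reductions are truncated at the 30% classification boundary
#: so generator group labels and the downstream >=30%-reduction rule agree
#: exactly.
RESPONDER_LAW = ReductionLaw(mean=0.55, sd=0.15, lo=0.30, hi=0.95)
NONRESPONDER_LAW = ReductionLaw(mean=0.10, sd=0.12, lo=-0.25, hi=0.29)


@dataclass
class CohortSpec:
    """Study-condition parameters for a two-group synthetic cohort.

    Defaults emulate the emulated study's conditions: 24 + 22 subjects,
    246 ROIs, 320 volumes at TR 1.6 s, group A (responders) with less
    head motion than group B, a CAPS baseline of 70.33 (15.3), and a
    planted nodal-hub difference between the groups' connectivity trees.
    """

    n_group_a: int = 24
    n_group_b: int = 22
    n_rois: int = 246
    n_volumes: int = 320
    tr_seconds: float = 1.6
    motion_scale_a: float = 1.0
    motion_scale_b: float = 1.5
    spike_rate: float = 0.02
    planted_tree_a: list[tuple[int, int]] | None = None
    planted_tree_b: list[tuple[int, int]] | None = None
    planted_hubs: list[int] | None = None
    hub_attachment: float = 0.5
    edge_signal_strength: float = 0.9
    noise_sd: float = 0.5
    motion_artifact_gain: float = 0.5
    caps_baseline_mean: float = 70.33
    caps_baseline_sd: float = 15.3
    response_fraction_a: float = 1.0
    response_fraction_b: float = 0.0
    responder_law: ReductionLaw = field(default_factory=lambda: replace(RESPONDER_LAW))
    nonresponder_law: ReductionLaw = field(
        default_factory=lambda: replace(NONRESPONDER_LAW)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 3:
            raise ValueError("n_rois must be >= 3")
        if self.n_volumes < 20:
            raise ValueError("n_volumes must be >= 20")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        for name in ("motion_scale_a", "motion_scale_b", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("spike_rate", "response_fraction_a", "response_fraction_b"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.edge_signal_strength < 1:
            raise ValueError("edge_signal_strength must lie in [0, 1)")
        if self.planted_hubs is None:
            n = self.n_rois
            self.planted_hubs = [n // 6, n // 2, (5 * n) // 6]
        # tree construction uses its own stream so cohort draws are unaffected
        ss = np.random.SeedSequence(self.seed, spawn_key=(7,))
        rng = np.random.default_rng(ss)
        if self.planted_tree_a is None:
            self.planted_tree_a = hub_spanning_tree(
                self.n_rois, self.planted_hubs, self.hub_attachment, rng=rng
            )
        if self.planted_tree_b is None:
            self.planted_tree_b = hub_spanning_tree(self.n_rois, [], 0.0, rng=rng)
        self.planted_tree_a = validate_spanning_tree(self.planted_tree_a, self.n_rois)
        self.planted_tree_b = validate_spanning_tree(self.planted_tree_b, self.n_rois)

    def adjacent_correlation(self) -> float:
        """Closed-form population correlation of tree-adjacent ROI pairs."""
        return self.edge_signal_strength / (1.0 + self.noise_sd**2)


@dataclass
class SubjectRecord:
    """One synthetic subject: motion, ROI/tissue series, clinical scores."""

    subject_id: str
    group: str  # "A" or "B"
    motion: MotionTrace
    roi_ts: RoiTimeSeries
    tissue_ts: dict[str, np.ndarray]
    caps_pre: float
    caps_post: float
    age: int
    education: int

    def __post_init__(self) -> None:
        T = self.roi_ts.n_volumes
        if self.motion.params.shape[0] != T:
            raise ValueError("motion trace length must equal n_volumes")
        for name, x in self.tissue_ts.items():
            if np.asarray(x).shape[0] != T:
                raise ValueError(f"tissue series {name!r} length mismatch")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def simulate_motion(
    n_volumes: int,
    scale: float,
    spike_rate: float,
    seed: int | np.random.SeedSequence = 0,
    return_spikes: bool = False,
):
    """Simulate a (T, 6) rigid-body parameter table (mm, mm, mm, rad, rad, rad).

    Each column is an AR(1) process (rho = 0.98) with innovation standard
    deviation proportional to ``scale``; with probability ``spike_rate``
    per volume an additive jump of 5-10x the innovation s.d. (random
    sign) is injected into one randomly chosen translation column.
    ``scale = 0`` yields an identically zero table (degenerate but valid);
    negative scale is an error.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if scale < 0:
        raise ValueError("scale must be non-negative")
    if not 0 <= spike_rate <= 1:
        raise ValueError("spike_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    innov_sd = np.array([_TRANS_INNOV_SD] * 3 + [_ROT_INNOV_SD] * 3) * scale
    innov = rng.normal(size=(n_volumes, 6)) * innov_sd
    spike_here = rng.random(n_volumes) < spike_rate
    spike_col = rng.integers(0, 3, size=n_volumes)
    spike_mag = rng.uniform(5.0, 10.0, size=n_volumes) * np.where(
        rng.random(n_volumes) < 0.5, -1.0, 1.0
    )
    spike_here[0] = False
    params = np.zeros((n_volumes, 6))
    for t in range(1, n_volumes):
        params[t] = _AR_RHO * params[t - 1] + innov[t]
        if spike_here[t]:
            c = spike_col[t]
            params[t, c] += spike_mag[t] * innov_sd[c]
    if return_spikes:
        return params, spike_here
    return params


def simulate_roi_timeseries(
    planted_tree,
    edge_signal_strength: float,
    noise_sd: float,
    n_volumes: int,
    seed: int | np.random.SeedSequence = 0,
    tr_seconds: float = 1.6,
    roi_labels: list[str] | None = None,
) -> RoiTimeSeries:
    """ROI time series whose correlation structure follows a planted tree.

    ROI pairs joined by a planted edge have population correlation
    ``a / (1 + sigma^2)`` (``a`` = edge_signal_strength, ``sigma`` =
    noise_sd); pairs at tree distance ``d`` have ``a^d / (1 + sigma^2)``,
    so planted edges always out-correlate non-edges.
    """
    n_nodes = 1 + len(list(planted_tree))
    edges = validate_spanning_tree(planted_tree, n_nodes)
    if not 0 <= edge_signal_strength < 1:
        raise ValueError("edge_signal_strength must lie in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    adj: list[list[int]] = [[] for _ in range(n_nodes)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    a = edge_signal_strength
    z = np.zeros((n_nodes, n_volumes))
    root = 0
    z[root] = _unit_ar1(rng, (n_volumes,))
    visited = np.zeros(n_nodes, dtype=bool)
    visited[root] = True
    queue = [root]
    for u in queue:
        for v in adj[u]:
            if not visited[v]:
                visited[v] = True
                # AR(1) innovations keep every latent unit-variance and
                # low-frequency-dominated, so tree correlations survive
                # band-pass filtering downstream
                z[v] = a * z[u] + np.sqrt(1 - a**2) * _unit_ar1(rng, (n_volumes,))
                queue.append(v)
    y = z + noise_sd * rng.normal(size=(n_nodes, n_volumes))
    if roi_labels is None:
        roi_labels = [f"ROI_{i + 1:03d}" for i in range(n_nodes)]
    return RoiTimeSeries(values=y, roi_labels=roi_labels, tr_seconds=tr_seconds)


def simulate_caps(
    group: str,
    spec: CohortSpec,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """Draw (caps_pre, caps_post) for one subject of the given group.

    caps_pre ~ Normal(baseline mean, sd) truncated at 0.  With the
    group's response fraction the fractional reduction comes from the
    responder law (mean > 0.30), otherwise from the non-responder law
    (mean < 0.30); caps_post = caps_pre * (1 - reduction), floored at 0.
    """
    if group not in ("A", "B"):
        raise ValueError("group must be 'A' or 'B'")
    rng = np.random.default_rng(seed)
    frac = spec.response_fraction_a if group == "A" else spec.response_fraction_b
    pre = -1.0
    while pre < 0:
        pre = rng.normal(spec.caps_baseline_mean, spec.caps_baseline_sd)
    law = spec.responder_law if rng.random() < frac else spec.nonresponder_law
    reduction = law.draw(rng)
    post = max(pre * (1.0 - reduction), 0.0)
    return float(pre), float(post)


def simulate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Generate the full cohort: n_group_a + n_group_b subject records.

    Per-subject randomness is derived deterministically from ``spec.seed``
    (SeedSequence spawn keyed by subject index), so identical specs yield
    byte-identical cohorts and subjects are mutually independent.
    """
    records = []
    n_total = spec.n_group_a + spec.n_group_b
    root_ss = np.random.SeedSequence(spec.seed)
    subject_seeds = root_ss.spawn(n_total)
    for idx in range(n_total):
        group = "A" if idx < spec.n_group_a else "B"
        scale = spec.motion_scale_a if group == "A" else spec.motion_scale_b
        tree = spec.planted_tree_a if group == "A" else spec.planted_tree_b
        sub_ss = subject_seeds[idx].spawn(4)

        params = simulate_motion(spec.n_volumes, scale, spec.spike_rate, sub_ss[0])
        motion = MotionTrace(params=params)
        roi_ts = simulate_roi_timeseries(
            tree,
            spec.edge_signal_strength,
            spec.noise_sd,
            spec.n_volumes,
            seed=sub_ss[1],
            tr_seconds=spec.tr_seconds,
        )
        rng = np.random.default_rng(sub_ss[2])
        # motion artifact: FD-locked global signal with per-ROI loadings,
        # removed downstream by spike regression / the Friston block
        if spec.motion_artifact_gain > 0:
            loadings = rng.normal(1.0, 0.2, size=spec.n_rois)
            artifact = spec.motion_artifact_gain * (motion.fd / 0.2)
            roi_ts.values += loadings[:, None] * artifact[None, :]
        gm = roi_ts.values.mean(axis=0) + 0.2 * rng.normal(size=spec.n_volumes)
        wm = _ar1(rng, spec.n_volumes, 0.9, 0.3)
        csf = _ar1(rng, spec.n_volumes, 0.9, 0.3)
        caps_pre, caps_post = simulate_caps(group, spec, sub_ss[3])
        records.append(
            SubjectRecord(
                subject_id=f"sub-{idx + 1:03d}",
                group=group,
                motion=motion,
                roi_ts=roi_ts,
                tissue_ts={"GM": gm, "WM": wm, "CSF": csf},
                caps_pre=caps_pre,
                caps_post=caps_post,
                age=int(rng.integers(23, 56)),
                education=int(rng.integers(2, 7)),
            )
        )
    return records


def _ar1(rng: np.random.Generator, T: int, rho: float, sd: float) -> np.ndarray:
    x = np.zeros(T)
    innov = rng.normal(scale=sd, size=T)
    for t in range(1, T):
        x[t] = rho * x[t - 1] + innov[t]
    return x


# ---------------------------------------------------------------------------
# On-disk layout
# ---------------------------------------------------------------------------


def write_cohort(records: list[SubjectRecord], outdir: str | Path) -> Path:
    """Write one directory per subject plus the cohort clinical table.

    Layout: ``<sub>/motion.txt`` (6 whitespace-delimited columns,
    translations mm then rotations rad), ``<sub>/roi_timeseries.tsv``
    (rows = labelled ROIs, columns = volumes), ``<sub>/tissue.tsv``
    (GM/WM/CSF columns), and ``cohort.csv`` (subject_id, group, caps_pre,
    caps_post, age, education).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        sdir = outdir / rec.subject_id
        sdir.mkdir(exist_ok=True)
        np.savetxt(sdir / "motion.txt", rec.motion.params, fmt="%.10f")
        ts = pd.DataFrame(
            rec.roi_ts.values,
            index=pd.Index(rec.roi_ts.roi_labels, name="roi"),
        )
        ts.to_csv(sdir / "roi_timeseries.tsv", sep="\t", float_format="%.6f")
        pd.DataFrame(rec.tissue_ts).to_csv(
            sdir / "tissue.tsv", sep="\t", index=False, float_format="%.6f"
        )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "caps_pre": rec.caps_pre,
                "caps_post": rec.caps_post,
                "age": rec.age,
                "education": rec.education,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "cohort.csv", index=False)
    return outdir
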