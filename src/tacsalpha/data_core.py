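"""Domain types, trial segmentation, adjacency, and the HDF5 container.

The experimental protocol this package analyses consists, per session
(``tacs`` or ``control``) and per block (``train10`` / ``train30``), of a
2-minute resting baseline followed by 20 stimulation trains separated by
15 s inter-stimulation intervals.  Post-stimulation data become usable only
3.8 s after train offset (device artifacts), and the analysis windows are
trimmed to 4.2-9.7 s after offset; the last 10 s of the baseline are
discarded and the remaining 110 s are cut into 20 epochs of 5.5 s.

All segment arithmetic lives here so every downstream stage shares the same
trial bookkeeping.  Epoch boundaries follow a half-open ``[start, end)``
convention at sample resolution, so a 5.5 s epoch at 1000 Hz holds exactly
5500 samples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np

SCHEMA_VERSION = "1"

#: usable window relative to train offset, seconds
POST_WINDOW = (3.8, 10.0)
#: final trimmed analysis window relative to train offset, seconds
POST_TRIM = (4.2, 9.7)
#: seconds removed from the end of the baseline
BASELINE_DISCARD = 10.0
#: baseline epoch length, seconds
BASELINE_EPOCH = 5.5

SESSIONS = ("tacs", "control")
BLOCKS = ("train10", "train30")


class ContainerSchemaError(RuntimeError):
    """Raised when an on-disk container does not match the expected schema."""


@dataclass(frozen=True)
class StudyDesign:
    """Protocol constants of one experiment.

    Defaults reproduce the study design: 20 intermittent stimulation trains
    per block (10 s or 30 s long), 15 s intervals, a 120 s baseline and
    1000 Hz sampling.
    """

    n_participants: int = 24
    sessions: tuple[str, ...] = SESSIONS
    blocks: tuple[str, ...] = BLOCKS
    trains_per_block: int = 20
    train_durations: dict[str, float] = field(
        default_factory=lambda: {"train10": 10.0, "train30": 30.0}
    )
    interval_duration: float = 15.0
    baseline_duration: float = 120.0
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.trains_per_block < 1:
            raise ValueError("trains_per_block must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        for blk in self.blocks:
            if blk not in self.train_durations:
                raise ValueError(f"missing train duration for block {blk!r}")
            if self.train_durations[blk] <= 0:
                raise ValueError("train durations must be > 0")
        if self.interval_duration <= 0 or self.baseline_duration <= 0:
            raise ValueError("durations must be > 0")

    def train_onsets(self, block: str) -> np.ndarray:
        """Nominal train onset times (s, session clock) for one block."""
        dur = self.train_durations[block]
        k = np.arange(self.trains_per_block)
        return self.baseline_duration + k * (dur + self.interval_duration)

    def block_duration(self, block: str) -> float:
        """Total recording length (s) of one block, baseline included."""
        dur = self.train_durations[block]
        return self.baseline_duration + self.trains_per_block * (
            dur + self.interval_duration
        )

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["sessions"] = list(self.sessions)
        d["blocks"] = list(self.blocks)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "StudyDesign":
        d = json.loads(s)
        d["sessions"] = tuple(d["sessions"])
        d["blocks"] = tuple(d["blocks"])
        return cls(**d)


@dataclass(frozen=True)
class UnitLayout:
    """Spatial layout of analysis units (sensors or source-grid points).

    ``adjacency`` is a symmetric, irreflexive boolean matrix; spatial
    clusters in the permutation test are connected components of the
    suprathreshold subgraph.  ``region_labels`` optionally assigns each unit
    to ``somatosensory``, ``frontal`` or ``other`` for the region split.
    """

    unit_ids: tuple[str, ...]
    coordinates: np.ndarray
    adjacency: np.ndarray
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.unit_ids)
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape != (n, n):
            raise ValueError("adjacency shape must be (n_units, n_units)")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        if self.coordinates.shape[0] != n:
            raise ValueError("coordinates must have one row per unit")
        if self.region_labels is not None and len(self.region_labels) != n:
            raise ValueError("region_labels must cover all units")
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(
            self, "coordinates", np.asarray(self.coordinates, dtype=float)
        )

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def units_in_region(self, region: str) -> np.ndarray:
        if self.region_labels is None:
            raise ValueError("layout has no region labels")
        return np.flatnonzero(np.asarray(self.region_labels) == region)

    def edge_list(self) -> np.ndarray:
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([iu, ju]).astype(np.int64)


def grid_layout(
    n_rows: int,
    n_cols: int,
    somatosensory: tuple[slice, slice] | None = None,
    frontal: tuple[slice, slice] | None = None,
) -> UnitLayout:
    """Rectangular unit lattice with 4-neighbour adjacency.

    ``somatosensory`` / ``frontal`` are (row-slice, col-slice) patches used
    as region labels; everything else is labelled ``other``.
    """
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    coords = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    n = n_rows * n_cols
    adj = np.zeros((n, n), dtype=bool)
    idx = np.arange(n).reshape(n_rows, n_cols)
    for a, b in ((idx[:-1, :], idx[1:, :]), (idx[:, :-1], idx[:, 1:])):
        adj[a.ravel(), b.ravel()] = True
        adj[b.ravel(), a.ravel()] = True
    labels = np.full(n, "other", dtype=object)
    for name, patch in (("somatosensory", somatosensory), ("frontal", frontal)):
        if patch is not None:
            mask = np.zeros((n_rows, n_cols), dtype=bool)
            mask[patch] = True
            labels[mask.ravel()] = name
    ids = tuple(f"u{r}_{c}" for r, c in coords.astype(int))
    return UnitLayout(ids, coords, adj, tuple(labels))


@dataclass
class TrialSet:
    """One class of epochs (baseline or post-stimulation) for one recording.

    data : float array, shape (n_units, n_trials, n_samples)
    time_axis : seconds; relative to train offset for post epochs, to
        segment start for baseline epochs.
    rejected_trials : bool flags; flagged trials are skipped, never removed,
        so trial order (needed by the binning analysis) is preserved.
    """

    data: np.ndarray
    time_axis: np.ndarray
    segment_class: str
    sampling_rate: float
    rejected_trials: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (unit, trial, sample)")
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        if self.time_axis.shape != (self.data.shape[2],):
            raise ValueError("time_axis length must equal sample count")
        if self.segment_class not in ("baseline", "post"):
            raise ValueError("segment_class must be 'baseline' or 'post'")
        if self.rejected_trials is None:
            self.rejected_trials = np.zeros(self.data.shape[1], dtype=bool)
        else:
            self.rejected_trials = np.asarray(self.rejected_trials, dtype=bool)

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    def good_trials(self) -> np.ndarray:
        return np.flatnonzero(~self.rejected_trials)


def _cut(continuous: np.ndarray, start_s: float, end_s: float, fs: float,
         what: str) -> np.ndarray:
    """Half-open [start, end) slice of a (unit, sample) array, with checks."""
    i0 = int(round(start_s * fs))
    i1 = int(round(end_s * fs))
    if i0 < 0 or i1 > continuous.shape[1]:
        raise ValueError(
            f"recording too short for {what}: needs samples [{i0}, {i1}) "
            f"but has {continuous.shape[1]}"
        )
    return continuous[:, i0:i1]


def segment_recording(
    continuous: np.ndarray,
    design: StudyDesign,
    train_onsets: np.ndarray,
    block: str,
) -> tuple[TrialSet, TrialSet]:
    """Cut one continuous block recording into baseline and post epochs.

    The first 110 s of the 120 s baseline are cut into 20 epochs of 5.5 s
    (the trailing 10 s are discarded).  For each train, the 3.8-10 s window
    after train offset is taken and trimmed to 4.2-9.7 s, yielding one 5.5 s
    post epoch per train.
    """
    continuous = np.asarray(continuous)
    if continuous.ndim != 2:
        raise ValueError("continuous must be (unit, sample)")
    fs = design.sampling_rate
    onsets = np.asarray(train_onsets, dtype=float)
    if onsets.ndim != 1 or len(onsets) != design.trains_per_block:
        raise ValueError(
            f"expected {design.trains_per_block} train onsets, got {len(onsets)}"
        )
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("train onsets must be strictly increasing")
    if onsets[0] < design.baseline_duration - 1e-9:
        raise ValueError("first train onset lies inside the baseline segment")
    dur = design.train_durations[block]
    if (onsets[-1] + dur + POST_WINDOW[1]) * fs > continuous.shape[1] + 1e-6:
        raise ValueError(
            "recording too short for the post segment of the final train"
        )

    # baseline: keep the first (baseline_duration - 10) s, epoch into 5.5 s
    keep = design.baseline_duration - BASELINE_DISCARD
    n_base = int(round(keep / BASELINE_EPOCH))
    base = _cut(continuous, 0.0, keep, fs, "baseline")
    n_ep = int(round(BASELINE_EPOCH * fs))
    base_epochs = base[:, : n_base * n_ep].reshape(base.shape[0], n_base, n_ep)
    t_base = np.arange(n_ep) / fs
    baseline = TrialSet(base_epochs, t_base, "baseline", fs)

    # post: [offset+4.2, offset+9.7) per train
    epochs = []
    for onset in onsets:
        off = onset + dur
        epochs.append(
            _cut(continuous, off + POST_TRIM[0], off + POST_TRIM[1], fs,
                 f"post epoch after train at {onset:g} s")
        )
    post_data = np.stack(epochs, axis=1)
    n_post = post_data.shape[2]
    t_post = POST_TRIM[0] + np.arange(n_post) / fs
    post = TrialSet(post_data, t_post, "post", fs)
    return baseline, post


def flag_artifact_trials(trials: TrialSet, zmax: float = 8.0) -> TrialSet:
    """Flag trials whose peak amplitude is an outlier of the pooled data.

    A robust z-score (median / 1.4826*MAD of all samples pooled over units
    and trials) is computed; a trial is flagged when any sample exceeds
    ``zmax`` in absolute robust z.  Flags are set, trials are never removed.
    """
    if zmax <= 0:
        raise ValueError("zmax must be > 0")
    pooled = trials.data.ravel()
    med = np.median(pooled)
    mad = np.median(np.abs(pooled - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = np.std(pooled) or 1.0
    peak_z = np.max(np.abs(trials.data - med), axis=(0, 2)) / scale
    flags = peak_z > zmax
    if flags.all():
        raise ValueError("no usable trials: every trial exceeds the threshold")
    out = TrialSet(
        trials.data, trials.time_axis, trials.segment_class,
        trials.sampling_rate, trials.rejected_trials | flags,
    )
    return out


# ---------------------------------------------------------------------------
# HDF5 container


def _write_trialset(grp: h5py.Group, ts: TrialSet) -> None:
    d = grp.create_dataset("data", data=ts.data)
    d.attrs["sampling_rate"] = ts.sampling_rate
    d.attrs["time_start"] = float(ts.time_axis[0])
    d.attrs["time_step"] = 1.0 / ts.sampling_rate
    d.attrs["segment_class"] = ts.segment_class
    grp.create_dataset("rejected", data=ts.rejected_trials)


def _read_trialset(grp: h5py.Group) -> TrialSet:
    d = grp["data"]
    n = d.shape[2]
    t0 = float(d.attrs["time_start"])
    dt = float(d.attrs["time_step"])
    return TrialSet(
        d[()], t0 + dt * np.arange(n), str(d.attrs["segment_class"]),
        float(d.attrs["sampling_rate"]), grp["rejected"][()],
    )


def write_container(
    path,
    design: StudyDesign,
    layout: UnitLayout,
    trialsets: dict[tuple[str, str, str], TrialSet],
    seed: int | None = None,
    metadata: dict | None = None,
) -> str:
    """Write a recording container.

    ``trialsets`` maps (session, block, segment_class) to a TrialSet.
    Arrays round-trip bit-identically; ``metadata`` (JSON-serialisable) is
    stored verbatim for provenance.
    """
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if seed is not None:
            f.attrs["seed"] = int(seed)
        f.attrs["metadata"] = json.dumps(metadata or {}, sort_keys=True)
        g = f.create_group("design")
        g.attrs["json"] = design.to_json()
        lay = f.create_group("layout")
        lay.create_dataset("coordinates", data=layout.coordinates)
        lay.create_dataset("edges", data=layout.edge_list())
        lay.create_dataset(
            "unit_ids", data=np.array(layout.unit_ids, dtype="S")
        )
        if layout.region_labels is not None:
            lay.create_dataset(
                "region_labels", data=np.array(layout.region_labels, dtype="S")
            )
        for (session, block, seg), ts in trialsets.items():
            grp = f.require_group(f"{session}/{block}/{seg}")
            _write_trialset(grp, ts)
    return str(path)


def read_container(path):
    """Read a container written by :func:`write_container`.

    Returns ``(design, layout, trialsets, info)`` where ``info`` carries the
    seed and metadata attributes.
    """
    with h5py.File(path, "r") as f:
        version = str(f.attrs.get("schema_version", "<missing>"))
        if version != SCHEMA_VERSION:
            raise ContainerSchemaError(
                f"schema version mismatch: expected {SCHEMA_VERSION}, "
                f"found {version}"
            )
        for required in ("design", "layout"):
            if required not in f:
                raise ContainerSchemaError(f"container missing group {required!r}")
        design = StudyDesign.from_json(f["design"].attrs["json"])
        lay = f["layout"]
        ids = tuple(s.decode() for s in lay["unit_ids"][()])
        edges = lay["edges"][()]
        n = len(ids)
        adj = np.zeros((n, n), dtype=bool)
        if len(edges):
            adj[edges[:, 0], edges[:, 1]] = True
            adj[edges[:, 1], edges[:, 0]] = True
        labels = None
        if "region_labels" in lay:
            labels = tuple(s.decode() for s in lay["region_labels"][()])
        layout = UnitLayout(ids, lay["coordinates"][()], adj, labels)
        trialsets: dict[tuple[str, str, str], TrialSet] = {}
        for session in design.sessions:
            if session not in f:
                continue
            for block in design.blocks:
                if block not in f[session]:
                    continue
                for seg in ("baseline", "post"):
                    if seg not in f[session][block]:
                        raise ContainerSchemaError(
                            f"container missing group {seg!r} under "
                            f"{session}/{block}"
                        )
                    trialsets[(session, block, seg)] = _read_trialset(
                        f[session][block][seg]
                    )
        info = {
            "seed": int(f.attrs["seed"]) if "seed" in f.attrs else None,
            "metadata": json.loads(f.attrs["metadata"])
            if "metadata" in f.attrs
            else {},
        }
    return design, layout, trialsets, info
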