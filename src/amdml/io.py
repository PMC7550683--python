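"""Reading Bonn-format EEG segments, the ten benchmark tasks, and view-file I/O.

Bonn segment files are plain ASCII: one numeric sample per line, no header.
Multi-view feature sets are stored as a single text file with a JSON header
followed by one full-precision matrix block per view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import DEFAULT_RATE, GROUPS, EEGSegment, MultiViewDataset


class BonnParseError(ValueError):
    """A segment or views file failed to parse."""


@dataclass(frozen=True)
class TaskSpec:
    """One binary classification task: positive groups vs negative groups."""

    task_id: int
    positive_groups: tuple[str, ...]
    negative_groups: tuple[str, ...]

    def __post_init__(self) -> None:
        pos, neg = set(self.positive_groups), set(self.negative_groups)
        if not pos or not neg:
            raise ValueError("both group sets must be non-empty")
        if pos & neg:
            raise ValueError("positive and negative groups overlap")
        unknown = (pos | neg) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")


#: The ten benchmark tasks over Bonn groups A-E.  The left-hand set is
#: labelled +1, the right-hand set -1.
TASKS: dict[int, TaskSpec] = {
    1: TaskSpec(1, ("A",), ("C",)),
    2: TaskSpec(2, ("A",), ("D",)),
    3: TaskSpec(3, ("A",), ("E",)),
    4: TaskSpec(4, ("B",), ("C",)),
    5: TaskSpec(5, ("B",), ("D",)),
    6: TaskSpec(6, ("B",), ("E",)),
    7: TaskSpec(7, ("A", "B"), ("C", "D")),
    8: TaskSpec(8, ("A", "B"), ("E",)),
    9: TaskSpec(9, ("A", "B"), ("D", "E")),
    10: TaskSpec(10, ("A", "B"), ("C", "E")),
}


def read_segment(
    path: str | Path,
    rate: float = DEFAULT_RATE,
    group: str | None = None,
) -> EEGSegment:
    """Read one Bonn-format segment file (one sample value per line).

    Blank lines are ignored.  A non-numeric line raises
    :class:`BonnParseError` naming the line number.
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                values.append(float(token))
            except ValueError:
                raise BonnParseError(
                    f"{path}: line {lineno}: not a number: {token!r}"
                ) from None
    if not values:
        raise BonnParseError(f"{path}: no samples found")
    return EEGSegment(
        samples=np.array(values), rate=rate, group=group, source_id=str(path)
    )


def load_group(
    directory: str | Path, group: str, rate: float = DEFAULT_RATE
) -> list[EEGSegment]:
    """Load every segment file in a group directory, sorted by filename."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise BonnParseError(f"{directory}: no segment files")
    return [read_segment(p, rate=rate, group=group) for p in files]


def build_task(
    segments_by_group: dict[str, list[EEGSegment]], spec: TaskSpec
) -> tuple[list[EEGSegment], np.ndarray]:
    """Assemble one task: positives first (+1), then negatives (-1).

    Ordering is stable within each group; groups appear in the order listed
    by the task spec.
    """
    for g in (*spec.positive_groups, *spec.negative_groups):
        if g not in segments_by_group:
            raise KeyError(f"task {spec.task_id} needs group {g!r}, not provided")
    segments: list[EEGSegment] = []
    labels: list[int] = []
    for g in spec.positive_groups:
        segments.extend(segments_by_group[g])
        labels.extend([+1] * len(segments_by_group[g]))
    for g in spec.negative_groups:
        segments.extend(segments_by_group[g])
        labels.extend([-1] * len(segments_by_group[g]))
    return segments, np.array(labels, dtype=int)


# ---------------------------------------------------------------------------
# Multi-view feature file format

_MAGIC = "# amdml-views 1"


def write_views(dataset: MultiViewDataset, path: str | Path) -> None:
    """Write a multi-view dataset to a single self-describing text file.

    Matrices are printed with ``%.17g`` so the round trip is bit-exact for
    finite float64 values.
    """
    path = Path(path)
    header = {
        "views": [
            {"name": name, "dim": int(X.shape[0])} for name, X in dataset.views
        ],
        "n_samples": int(dataset.n_samples),
        "labels": [int(v) for v in dataset.labels],
        "meta": dataset.meta,
    }
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(json.dumps(header) + "\n")
        for name, X in dataset.views:
            fh.write(f"# view {name}\n")
            np.savetxt(fh, X, fmt="%.17g", delimiter="\t")


def read_views(path: str | Path) -> MultiViewDataset:
    """Read a views file written by :func:`write_views`, validating shapes."""
    path = Path(path)
    with open(path) as fh:
        magic = fh.readline().rstrip("\n")
        if magic != _MAGIC:
            raise BonnParseError(f"{path}: not an amdml views file")
        try:
            header = json.loads(fh.readline())
        except json.JSONDecodeError as exc:
            raise BonnParseError(f"{path}: bad header: {exc}") from None
        n = int(header["n_samples"])
        labels = np.array(header["labels"], dtype=int)
        if labels.size != n:
            raise BonnParseError(f"{path}: label count {labels.size} != N={n}")
        views: list[tuple[str, np.ndarray]] = []
        for vh in header["views"]:
            marker = fh.readline().rstrip("\n")
            if marker != f"# view {vh['name']}":
                raise BonnParseError(
                    f"{path}: expected view block {vh['name']!r}, got {marker!r}"
                )
            rows = []
            for _ in range(int(vh["dim"])):
                line = fh.readline()
                if not line:
                    raise BonnParseError(
                        f"{path}: view {vh['name']!r} truncated"
                    )
                try:
                    row = np.array(line.split(), dtype=float)
                except ValueError as exc:
                    raise BonnParseError(
                        f"{path}: view {vh['name']!r}: {exc}"
                    ) from None
                if row.size != n:
                    raise BonnParseError(
                        f"{path}: view {vh['name']!r} row has {row.size} "
                        f"entries, expected {n}"
                    )
                rows.append(row)
            views.append((vh["name"], np.vstack(rows)))
    return MultiViewDataset(views=views, labels=labels, meta=header.get("meta", {}))
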