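"""Cavity-composition statistics for explanted subretinal implants.

After chronic implantation the residual retina molds into the implant wells;
confocal counting yields, per cavity, the number of bipolar cells (the
stimulation target), glial cells, and all other cell types.  Because cavity
volume varies with well width and pillar count, counts are first normalized
to percentages within each cavity, and groups (by cavity width or by number
of protuberances) are then summarized by the unweighted mean ± sample
standard deviation of those per-cavity percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASSES = ("bipolar", "glial", "other")
GROUPINGS = ("width", "n_protuberances")


@dataclass(frozen=True)
class CavityObservation:
    """Cell counts of one cavity with its design covariates."""

    cavity_id: str
    cavity_width_um: float
    n_protuberances: int
    count_bipolar: int
    count_glial: int
    count_other: int

    def __post_init__(self) -> None:
        counts = (self.count_bipolar, self.count_glial, self.count_other)
        if any(int(c) != c or c < 0 for c in counts):
            raise ValueError("counts must be non-negative integers")
        if self.n_protuberances not in (0, 1, 2, 3, 4):
            raise ValueError("n_protuberances must be in 0..4")

    @property
    def total(self) -> int:
        return self.count_bipolar + self.count_glial + self.count_other


@dataclass(frozen=True)
class CompositionSummary:
    """Mean ± SD percentage per cell class for one group of cavities."""

    grouping: str
    group_key: float
    mean_pct: dict
    sd_pct: dict
    n_cavities: int


def normalize_counts(obs: CavityObservation) -> dict | None:
    """Per-class percentages of one cavity (sum exactly 100), or None if the
    cavity is empty (zero total — flagged for exclusion, not an error)."""
    total = obs.total
    if total == 0:
        return None
    return {
        "bipolar": 100.0 * obs.count_bipolar / total,
        "glial": 100.0 * obs.count_glial / total,
        "other": 100.0 * obs.count_other / total,
    }


def summarize_by(observations: list[CavityObservation],
                 grouping: str = "width") -> list[CompositionSummary]:
    """Group composition summaries, ordered by ascending group key.

    The statistic is the unweighted mean and sample (n−1) standard deviation
    of per-cavity percentages — cavities are the replication unit, not cells.
    Empty cavities are excluded; empty groups are omitted.  Single-cavity
    groups report SD = 0.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    key = (lambda o: o.cavity_width_um) if grouping == "width" else (
        lambda o: o.n_protuberances
    )
    buckets: dict[float, list[dict]] = {}
    for obs in observations:
        pct = normalize_counts(obs)
        if pct is None:
            continue
        buckets.setdefault(key(obs), []).append(pct)

    out = []
    for gkey in sorted(buckets):
        rows = buckets[gkey]
        mat = np.array([[r[c] for c in CLASSES] for r in rows])
        # canonical row order: summaries are bitwise permutation-invariant
        mat = mat[np.lexsort(mat.T[::-1])]
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1) if len(rows) > 1 else np.zeros(len(CLASSES))
        out.append(
            CompositionSummary(
                grouping=grouping,
                group_key=float(gkey),
                mean_pct=dict(zip(CLASSES, mean.tolist())),
                sd_pct=dict(zip(CLASSES, sd.tolist())),
                n_cavities=len(rows),
            )
        )
    return out


def design_table() -> dict:
    """Exploitable-cavity counts of the in vivo study design.

    Used to validate synthetic datasets: 27 cavities entered the width
    comparison (16 of 100 µm, 8 of 80 µm, 3 of 60 µm) and 44 the
    protuberance-count comparison (12/7/9/9/7 cavities with 0–4 pillars).
    """
    return {
        "width": {100: 16, 80: 8, 60: 3},
        "n_protuberances": {0: 12, 1: 7, 2: 9, 3: 9, 4: 7},
    }


# ---------------------------------------------------------------------------
# CSV I/O

_CSV_COLUMNS = [
    "cavity_id", "width_um", "n_protuberances",
    "count_bipolar", "count_glial", "count_other",
]


def write_cavity_csv(path, observations: list[CavityObservation]) -> None:
    df = pd.DataFrame(
        [
            {
                "cavity_id": o.cavity_id,
                "width_um": o.cavity_width_um,
                "n_protuberances": o.n_protuberances,
                "count_bipolar": o.count_bipolar,
                "count_glial": o.count_glial,
                "count_other": o.count_other,
            }
            for o in observations
        ],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_cavity_csv(path) -> list[CavityObservation]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cavity CSV missing columns: {sorted(missing)}")
    return [
        CavityObservation(
            cavity_id=str(r.cavity_id),
            cavity_width_um=float(r.width_um),
            n_protuberances=int(r.n_protuberances),
            count_bipolar=int(r.count_bipolar),
            count_glial=int(r.count_glial),
            count_other=int(r.count_other),
        )
        for r in df.itertuples()
    ]


def summaries_to_frame(summaries: list[CompositionSummary]) -> pd.DataFrame:
    """Long-format table (group, class, mean_pct, sd_pct, n) for CSV export."""
    rows = []
    for s in summaries:
        for c in CLASSES:
            rows.append(
                {
                    "grouping": s.grouping,
                    "group": s.group_key,
                    "cell_class": c,
                    "mean_pct": s.mean_pct[c],
                    "sd_pct": s.sd_pct[c],
                    "n_cavities": s.n_cavities,
                }
            )
    return pd.DataFrame(rows)
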