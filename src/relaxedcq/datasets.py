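"""Mammographic-mass data handling and synthetic generators.

The real-data path reads the UCI mammographic-mass CSV dialect: six
comma-separated fields per line — BI-RADS assessment, patient age, mass
shape, mass margin, mass density, severity — with ``?`` marking a missing
value and no header row.  Severity is the binary ground truth (0 benign,
1 malignant).

Two synthetic generators make the whole stack testable offline:
feasible split-feasibility instances with a planted solution, and
two-class Gaussian feature tables whose marginal means/sds default to the
published summary statistics of the mammographic-mass attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .elm import TrainingSet
from .geometry import (
    SFPInstance,
    ball_set_constraint,
    l1_ball_constraint,
    l2_ball_constraint,
    singleton_constraint,
)

__all__ = [
    "MammoRecord",
    "SyntheticSpec",
    "FIELDS",
    "FIELD_RANGES",
    "TABLE_MARGINALS",
    "read_mammo_csv",
    "write_mammo_csv",
    "clean",
    "make_sfp_instance",
    "make_classification_table",
]

FIELDS = ("birads", "age", "shape", "margin", "density", "severity")

# published attribute ranges; cleaning drops anything outside them
FIELD_RANGES = {
    "birads": (1, 6),
    "age": (18, 96),
    "shape": (1, 4),
    "margin": (1, 5),
    "density": (1, 4),
    "severity": (0, 1),
}

# per-attribute (mean, sd) summary statistics of the real data set,
# used as default marginals by the synthetic table generator
TABLE_MARGINALS = {
    "birads": (4.33, 0.63),
    "age": (55.78, 14.67),
    "shape": (2.78, 1.24),
    "margin": (2.81, 1.57),
    "density": (2.92, 0.35),
}


class MammoRecord(NamedTuple):
    """One mammographic-mass case; ``None`` marks a missing field."""

    birads: Optional[int]
    age: Optional[int]
    shape: Optional[int]
    margin: Optional[int]
    density: Optional[int]
    severity: Optional[int]


def read_mammo_csv(path: str | Path) -> tuple[list[MammoRecord], dict[str, int]]:
    """Parse a UCI-dialect CSV into records plus a per-field missing count.

    No cleaning is applied; records keep their ``None`` entries so the
    missing-value report can be audited before anything is dropped.
    """
    records: list[MammoRecord] = []
    missing = {f: 0 for f in FIELDS}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(FIELDS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(FIELDS)} comma-separated "
                    f"fields, got {len(parts)}"
                )
            vals = []
            for name, tok in zip(FIELDS, parts):
                tok = tok.strip()
                if tok == "?":
                    vals.append(None)
                    missing[name] += 1
                else:
                    vals.append(int(round(float(tok))))
            records.append(MammoRecord(*vals))
    return records, missing


def write_mammo_csv(records: Sequence[MammoRecord], path: str | Path) -> None:
    """Write records back in the same dialect (``?`` for missing)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(",".join("?" if v is None else str(v) for v in rec) + "\n")


def clean(records: Sequence[MammoRecord]) -> TrainingSet:
    """Drop incomplete records, then drop out-of-range outliers.

    The outlier rule keeps only records whose every field lies inside the
    published attribute range (BI-RADS 1-6, age 18-96, shape 1-4,
    margin 1-5, density 1-4, severity 0/1).  Order-independent and
    idempotent: both rules are pure per-record predicates.
    """
    kept = []
    for rec in records:
        if any(v is None for v in rec):
            continue
        if all(FIELD_RANGES[f][0] <= v <= FIELD_RANGES[f][1] for f, v in zip(FIELDS, rec)):
            kept.append(rec)
    if not kept:
        raise ValueError("cleaning removed every record")
    arr = np.asarray(kept, dtype=float)
    return TrainingSet(features=arr[:, :5], targets=arr[:, 5])


def as_dataframe(records: Sequence[MammoRecord]) -> pd.DataFrame:
    """Records as a pandas DataFrame with nullable integer columns."""
    return pd.DataFrame(records, columns=FIELDS).astype("Int64")


# ---------------------------------------------------------------------------
# Synthetic generators


@dataclass
class SyntheticSpec:
    """Recipe for a two-class Gaussian feature table.

    ``cluster_separation`` is the between-class mean shift in units of each
    attribute's sd (applied symmetrically, so the class means sit
    +/- separation/2 sds from the marginal mean).  ``marginals`` maps the
    attribute order to (mean, sd) pairs and defaults to the published
    mammographic-mass summary statistics; ``integerize`` rounds ordinal
    attributes into their published ranges, emulating the discreteness of
    the real table.
    """

    n_samples: int = 961
    class_balance: float = 0.463  # malignant fraction of the real data (445/961)
    cluster_separation: float = 1.0
    marginals: dict = field(default_factory=lambda: dict(TABLE_MARGINALS))
    integerize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")

    @property
    def n_features(self) -> int:
        return len(self.marginals)


def make_classification_table(spec: SyntheticSpec) -> TrainingSet:
    """Draw a binary-labelled Gaussian-cluster table with the spec marginals.

    Positive-class rows have each attribute mean shifted up by
    ``separation/2`` sds and negative-class rows shifted down, so the
    pooled marginal mean stays on target for a balanced draw.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_samples * spec.class_balance))
    n_pos = min(max(n_pos, 1), spec.n_samples - 1) if spec.n_samples > 1 else n_pos
    labels = np.zeros(spec.n_samples)
    labels[:n_pos] = 1.0
    rng.shuffle(labels)

    names = list(spec.marginals)
    means = np.array([spec.marginals[f][0] for f in names])
    sds = np.array([spec.marginals[f][1] for f in names])
    shift = 0.5 * spec.cluster_separation * sds
    centers = means + np.where(labels[:, None] == 1.0, shift, -shift)
    X = rng.normal(loc=centers, scale=sds)

    if spec.integerize:
        for j, f in enumerate(names):
            lo, hi = FIELD_RANGES.get(f, (-np.inf, np.inf))
            X[:, j] = np.clip(np.round(X[:, j]), lo, hi)
    return TrainingSet(features=X, targets=labels)


def make_sfp_instance(
    m: int = 20,
    n: int = 10,
    constraint: str = "l2_ball",
    gamma: Optional[float] = None,
    q_kind: str = "ball",
    q_radius: float = 0.1,
    seed: int = 0,
) -> SFPInstance:
    """Random feasible split-feasibility instance with a planted solution.

    ``A`` is a standard Gaussian m x n matrix.  The planted point ``w*`` is
    drawn and rescaled to sit at half the norm budget, strictly inside C
    (gamma defaults to 7 for the L1 ball and 17 for the L2 ball,
    matching the classifier's regularization budgets).  Q either contains
    ``A w*`` with a margin (``q_kind='ball'``, radius ``q_radius``) or is
    the singleton ``{A w*}``.  The solution set is nonempty by
    construction and ``w*`` is recorded on the instance.
    """
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((m, n))
    w = rng.standard_normal(n)
    if constraint == "l1_ball":
        gamma = 7.0 if gamma is None else gamma
        Cset = l1_ball_constraint(gamma)
        w_star = 0.5 * gamma * w / np.abs(w).sum()
    elif constraint == "l2_ball":
        gamma = 17.0 if gamma is None else gamma
        Cset = l2_ball_constraint(gamma)
        w_star = 0.5 * np.sqrt(gamma) * w / np.linalg.norm(w)
    else:
        raise ValueError("constraint must be 'l1_ball' or 'l2_ball'")
    target = A @ w_star
    if q_kind == "ball":
        Qset = ball_set_constraint(target, q_radius)
    elif q_kind == "singleton":
        Qset = singleton_constraint(target)
    else:
        raise ValueError("q_kind must be 'ball' or 'singleton'")
    return SFPInstance(
        A=A,
        Cset=Cset,
        Qset=Qset,
        known_solution=w_star,
        meta={"constraint": constraint, "gamma": gamma, "q_kind": q_kind, "seed": seed},
    )
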