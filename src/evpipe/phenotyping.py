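"""Tetraspanin phenotype calling and per-sample summaries.

A cluster is positive in a channel when strictly more than ``threshold``
member molecules of that channel lie within ``radius`` nm of the cluster
centre (defaults: 3 molecules, 150 nm).  The two channel booleans map to
phenotypes CD81-only (channel 1), CD9-only (channel 2), double positive, or
none.  Fractions are reported over positive clusters only, so the three
phenotype fractions sum to 1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 3
DEFAULT_RADIUS_NM = 150.0

PHENOTYPES = ("CD81_only", "CD9_only", "double_positive")


class Phenotype(str, enum.Enum):
    CD81_only = "CD81_only"
    CD9_only = "CD9_only"
    double_positive = "double_positive"
    none = "none"


@dataclass
class PhenotypeSummary:
    """Counts and fractions per phenotype, with per-FOV replicate statistics."""

    counts: dict[str, int]
    fractions: dict[str, float]
    n_fov: int
    per_fov: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    fov_mean: dict[str, float] = field(default_factory=dict)
    fov_sd: dict[str, float] = field(default_factory=dict)
    no_positives: bool = False

    @property
    def n_positive(self) -> int:
        return sum(self.counts.values())


def _assign(ch1_pos: bool, ch2_pos: bool) -> Phenotype:
    if ch1_pos and ch2_pos:
        return Phenotype.double_positive
    if ch1_pos:
        return Phenotype.CD81_only
    if ch2_pos:
        return Phenotype.CD9_only
    return Phenotype.none


def call_phenotype(
    centre: tuple[float, float],
    mol_xy: np.ndarray,
    mol_channel: np.ndarray,
    threshold: int = DEFAULT_THRESHOLD,
    radius: float = DEFAULT_RADIUS_NM,
) -> tuple[Phenotype, int, int]:
    """Call one cluster. Returns (phenotype, ch1 count, ch2 count in radius)."""
    mol_xy = np.asarray(mol_xy, dtype=float)
    mol_channel = np.asarray(mol_channel)
    d2 = ((mol_xy - np.asarray(centre, float)) ** 2).sum(axis=1)
    near = d2 <= radius**2
    n1 = int(((mol_channel == 1) & near).sum())
    n2 = int(((mol_channel == 2) & near).sum())
    return _assign(n1 > threshold, n2 > threshold), n1, n2


def call_phenotypes(
    clusters: pd.DataFrame,
    molecules: pd.DataFrame,
    assignment: np.ndarray,
    threshold: int = DEFAULT_THRESHOLD,
    radius: float = DEFAULT_RADIUS_NM,
) -> pd.DataFrame:
    """Call every cluster; returns one row per cluster.

    Columns: cluster_id, ch1_molecules_within_radius,
    ch2_molecules_within_radius, phenotype.  Counting is restricted to the
    cluster's own member molecules (``assignment`` aligns molecule rows to
    cluster ids).
    """
    mol_xy = molecules[["x", "y"]].to_numpy(float)
    mol_ch = molecules["channel"].to_numpy()
    rows = []
    for _, cl in clusters.iterrows():
        members = assignment == cl["cluster_id"]
        pheno, n1, n2 = call_phenotype(
            (cl["x"], cl["y"]), mol_xy[members], mol_ch[members], threshold, radius
        )
        rows.append((int(cl["cluster_id"]), n1, n2, pheno.value))
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "ch1_molecules_within_radius",
            "ch2_molecules_within_radius",
            "phenotype",
        ],
    )


def summarize(
    calls: pd.DataFrame, fov_labels: np.ndarray | pd.Series | None = None
) -> PhenotypeSummary:
    """Summarize phenotype calls into counts and positive-only fractions.

    ``fov_labels`` (one per call) enables per-FOV mean +/- SD of the
    fractions; without them the summary is a single pooled replicate.
    """
    if len(calls) == 0:
        raise ValueError("no phenotype calls to summarize")
    pheno = calls["phenotype"].astype(str)
    counts = {p: int((pheno == p).sum()) for p in PHENOTYPES}
    n_pos = sum(counts.values())
    if n_pos == 0:
        return PhenotypeSummary(
            counts=counts,
            fractions={p: float("nan") for p in PHENOTYPES},
            n_fov=0,
            no_positives=True,
        )
    fractions = {p: counts[p] / n_pos for p in PHENOTYPES}

    if fov_labels is None:
        fov_labels = np.zeros(len(calls), dtype=int)
    fov_labels = np.asarray(fov_labels)
    per_fov_rows = []
    for fov in pd.unique(fov_labels):
        sub = pheno[fov_labels == fov]
        pos = sum(int((sub == p).sum()) for p in PHENOTYPES)
        if pos == 0:
            continue
        per_fov_rows.append(
            {"fov": fov, **{p: int((sub == p).sum()) / pos for p in PHENOTYPES}}
        )
    per_fov = pd.DataFrame(per_fov_rows)
    fov_mean = {p: float(per_fov[p].mean()) for p in PHENOTYPES} if len(per_fov) else {}
    fov_sd = (
        {p: float(per_fov[p].std(ddof=1)) for p in PHENOTYPES}
        if len(per_fov) > 1
        else {p: float("nan") for p in PHENOTYPES}
    )
    return PhenotypeSummary(
        counts=counts,
        fractions=fractions,
        n_fov=len(per_fov),
        per_fov=per_fov,
        fov_mean=fov_mean,
        fov_sd=fov_sd,
    )


def summarize_counts(n_cd81: int, n_cd9: int, n_dp: int) -> PhenotypeSummary:
    """Summary straight from per-phenotype totals (single replicate)."""
    calls = pd.DataFrame(
        {
            "phenotype": ["CD81_only"] * n_cd81
            + ["CD9_only"] * n_cd9
            + ["double_positive"] * n_dp
        }
    )
    return summarize(calls)


def compare_to_control(
    sample: PhenotypeSummary, control: PhenotypeSummary, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-way ANOVA (group x phenotype) on per-FOV fractions.

    Routine convenience only; nothing downstream depends on it.  Requires at
    least two FOV replicates per group.  Returns the ANOVA table augmented
    with a ``significant`` column at the given alpha.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for name, s in (("sample", sample), ("control", control)):
        if len(s.per_fov) < 2:
            raise ValueError(f"{name} has fewer than 2 FOV replicates")
    long = []
    for group, s in (("sample", sample), ("control", control)):
        for _, row in s.per_fov.iterrows():
            for p in PHENOTYPES:
                long.append({"group": group, "phenotype": p, "fraction": row[p]})
    df = pd.DataFrame(long)
    model = ols("fraction ~ C(group) * C(phenotype)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table["significant"] = table["PR(>F)"] < alpha
    return table
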