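"""Three-comparison differential-expression intersection with direction
concordance.

The procedure identifies genes whose expression is regulated by O2
experience through a specific sensor pathway, from three pairwise
comparisons over one gene universe:

* t1 — responder strain, low vs high O2 (O2-modulated genes);
* t2 — sensor mutant vs responder at high O2 (pathway-dependent genes);
* t3 — sensor mutant, low vs high O2 (pathway-independent O2 effects).

With significance defined as q < 0.05 (strict), the final set is

    final = (sig(t1) ∩ sig(t2)) \\ sig(t3)

i.e. genes O2-regulated in the responder, also altered by losing the
sensor, but not altered by O2 in the mutant.  Concordance counts final-set
genes whose oriented effect signs agree between t1 and t2: lowering O2 and
disrupting the sensor pathway should shift expression the same way.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DETable",
    "IntersectionReport",
    "validate_de_table",
    "significant_set",
    "intersect_report",
]

REQUIRED_COLUMNS = ("gene_id", "log2fc", "q_value")


@dataclass(frozen=True)
class DETable:
    """One pairwise comparison's gene-level differential-test output.

    ``orientation`` is +1 if the stored log2fc sign already points in the
    comparison's biological direction of interest (e.g. effect of lowering
    O2, or of losing the sensor), -1 to flip a table stored the other way
    around.
    """

    data: pd.DataFrame
    name: str = ""
    orientation: int = 1

    def __post_init__(self) -> None:
        validate_de_table(self.data)
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.data["gene_id"])

    def oriented_sign(self) -> pd.Series:
        s = np.sign(self.data["log2fc"]) * self.orientation
        return pd.Series(s.to_numpy(), index=self.data["gene_id"].to_numpy())

    def q_series(self) -> pd.Series:
        return pd.Series(
            self.data["q_value"].to_numpy(), index=self.data["gene_id"].to_numpy()
        )


def validate_de_table(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()[:5]
        raise ValueError(f"duplicate gene ids, e.g. {list(dups)}")
    q = df["q_value"]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("q_value must lie in [0, 1]")


def significant_set(table, q_cut: float = 0.05) -> set:
    """Genes with q strictly below the cutoff."""
    df = table.data if isinstance(table, DETable) else table
    validate_de_table(df)
    return set(df.loc[df["q_value"] < q_cut, "gene_id"])


@dataclass
class IntersectionReport:
    """Counts and gene lists of the three-way intersection."""

    n_s1: int
    n_s1_and_s2: int
    n_final: int
    n_concordant: int
    s1: set = field(repr=False, default_factory=set)
    s1_and_s2: set = field(repr=False, default_factory=set)
    final: set = field(repr=False, default_factory=set)
    concordant: set = field(repr=False, default_factory=set)
    q_cut: float = 0.05

    def to_json(self, path=None) -> str:
        payload = {
            "q_cut": self.q_cut,
            "n_s1": self.n_s1,
            "n_s1_and_s2": self.n_s1_and_s2,
            "n_final": self.n_final,
            "n_concordant": self.n_concordant,
            "final_genes": sorted(self.final),
            "concordant_genes": sorted(self.concordant),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _as_table(t, name: str) -> DETable:
    return t if isinstance(t, DETable) else DETable(t, name=name)


def intersect_report(
    t1,
    t2,
    t3,
    q_cut: float = 0.05,
    q_cut_exclusion: float | None = None,
    allow_missing: bool = False,
) -> IntersectionReport:
    """Run the three-way intersection.

    ``q_cut_exclusion`` is the cutoff applied to t3 when deciding "not
    significantly altered" (defaults to ``q_cut``).  Tables must share a
    gene universe; with ``allow_missing=True`` genes absent from a table
    are treated as non-significant (q = 1) with a warning instead of
    rejecting.
    """
    t1 = _as_table(t1, "t1")
    t2 = _as_table(t2, "t2")
    t3 = _as_table(t3, "t3")
    q_cut_exclusion = q_cut if q_cut_exclusion is None else q_cut_exclusion

    universes = [set(t.genes) for t in (t1, t2, t3)]
    union = set.union(*universes)
    if any(u != union for u in universes):
        if not allow_missing:
            diffs = {
                t.name or f"t{i+1}": sorted(union - u)[:10]
                for i, (t, u) in enumerate(zip((t1, t2, t3), universes))
                if u != union
            }
            raise ValueError(f"gene universes differ; missing examples: {diffs}")
        warnings.warn(
            "gene universes differ; missing genes treated as q=1",
            stacklevel=2,
        )

    s1 = significant_set(t1, q_cut)
    s2 = significant_set(t2, q_cut)
    s3 = significant_set(t3, q_cut_exclusion)
    s12 = s1 & s2
    final = s12 - s3

    sign1 = t1.oriented_sign()
    sign2 = t2.oriented_sign()
    concordant = {
        g
        for g in final
        if g in sign1.index and g in sign2.index and sign1[g] == sign2[g] and sign1[g] != 0
    }
    return IntersectionReport(
        n_s1=len(s1),
        n_s1_and_s2=len(s12),
        n_final=len(final),
        n_concordant=len(concordant),
        s1=s1,
        s1_and_s2=s12,
        final=final,
        concordant=concordant,
        q_cut=q_cut,
    )
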