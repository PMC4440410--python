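"""Synthetic differential-expression tables with programmed Venn structure.

Produces three gene-level DE tables (gene_id, log2fc, q_value) — one per
pairwise comparison — whose significant sets realize an exact three-set
Venn design, with a programmed probability that genes shared between
comparisons change in the same (oriented) direction.

q-values of significant genes are drawn uniformly on [0, 0.049] and of
non-significant genes on [0.06, 1], keeping every gene clear of the 0.05
decision boundary so set membership is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Venn region keys: a 3-character string of 0/1 flags, one per table,
#: e.g. "110" = significant in tables 1 and 2 but not 3.
VENN_REGIONS = ("100", "010", "001", "110", "101", "011", "111")

__all__ = ["SyntheticDEConfig", "gen_de_tables", "VENN_REGIONS"]


@dataclass(frozen=True)
class SyntheticDEConfig:
    """Design of the synthetic three-comparison DE experiment.

    overlap_design maps Venn region keys (see :data:`VENN_REGIONS`) to the
    number of genes significant in exactly that combination of tables.
    ``concordance`` is the probability that a gene significant in several
    tables has the same effect sign in all of them; the realized count is
    deterministic, ``round(concordance * n_region)`` per region, so exact
    designs are reproducible.
    """

    n_genes: int = 5000
    overlap_design: dict = field(default_factory=dict)
    frac_sig_each: float | None = None
    concordance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError("concordance must be in [0, 1]")
        if self.frac_sig_each is not None and not 0.0 <= self.frac_sig_each <= 1.0:
            raise ValueError("frac_sig_each must be in [0, 1]")
        design = self.resolved_design()
        bad = set(design) - set(VENN_REGIONS)
        if bad:
            raise ValueError(f"unknown Venn regions {sorted(bad)}")
        if any(v < 0 for v in design.values()):
            raise ValueError("Venn counts must be non-negative")
        if sum(design.values()) > self.n_genes:
            raise ValueError("Venn design exceeds the gene universe")

    def resolved_design(self) -> dict:
        if self.overlap_design:
            return dict(self.overlap_design)
        if self.frac_sig_each is None:
            return {}
        # independent per-table significance, no programmed overlap
        k = int(round(self.frac_sig_each * self.n_genes))
        return {"100": k, "010": k, "001": k} if k else {}


def gen_de_tables(
    config: SyntheticDEConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate three DE tables realizing ``config``.

    Returns three DataFrames with columns gene_id, log2fc, q_value over a
    shared gene universe.  Effect signs of genes shared between tables are
    concordant (same oriented sign in every table where significant) for a
    deterministic ``round(concordance * n)`` subset of each shared region.
    """
    design = config.resolved_design()
    rng = np.random.default_rng(config.seed)
    ids = np.array([f"gene{idx:05d}" for idx in range(config.n_genes)])
    perm = rng.permutation(config.n_genes)

    # allocate genes to regions from a seeded permutation
    region_genes: dict[str, np.ndarray] = {}
    cursor = 0
    for region in VENN_REGIONS:
        k = int(design.get(region, 0))
        region_genes[region] = perm[cursor : cursor + k]
        cursor += k

    tables = []
    sig_mask = np.zeros((3, config.n_genes), bool)
    for t in range(3):
        for region, genes in region_genes.items():
            if region[t] == "1":
                sig_mask[t, genes] = True

    base_sign = rng.choice([-1.0, 1.0], config.n_genes)
    # per-table signs: table 0 uses the base sign; shared genes in later
    # tables copy it for the concordant subset and flip it otherwise
    signs = np.tile(base_sign, (3, 1))
    for region, genes in region_genes.items():
        tables_in = [t for t in range(3) if region[t] == "1"]
        if len(tables_in) < 2 or len(genes) == 0:
            continue
        n_conc = int(round(config.concordance * len(genes)))
        disc = rng.permutation(genes)[n_conc:]
        for t in tables_in[1:]:
            signs[t, disc] = -base_sign[disc]

    out = []
    for t in range(3):
        q = rng.uniform(0.06, 1.0, config.n_genes)
        q[sig_mask[t]] = rng.uniform(0.0, 0.049, int(sig_mask[t].sum()))
        mag = np.where(
            sig_mask[t],
            rng.uniform(0.5, 4.0, config.n_genes),
            rng.uniform(0.0, 0.4, config.n_genes),
        )
        out.append(
            pd.DataFrame(
                {"gene_id": ids, "log2fc": signs[t] * mag, "q_value": q}
            )
        )
    return tuple(out)
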