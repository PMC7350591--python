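"""The strain-viability conflict census: genes whose KO-first (tm1a / em)
and post-Cre (tm1b) alleles were assigned different viability classes.

Such discordance is a signature of residual-product rescue: the two alleles
of one gene should phenocopy each other, and when they do not, one of them
is probably not a true null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import pandas as pd

VIABILITY_CLASSES = ("viable", "subviable", "lethal")
ALLELE_LABELS = ("tm1a", "tm1b")  # em-series accepted as em<digit>

#: Denominator of the published IMPC conditional-ready strain census.
IMPC_N_STRAINS = 427

# 17 genes with discordant allele classes in the published IMPC census.
# Gene symbols and allele labels are as printed; class-column placement is
# only partially recoverable from the flattened table, so classes are
# RECONSTRUCTED: the three genes also described in prose carry their stated
# classes, the rest are assigned (viable, lethal). The census uses only the
# fact that the two classes differ.
_TABLE1_ROWS = [
    ("Bbox1", "em1", "viable", "tm1b", "lethal"),
    ("Caskin1", "em1", "viable", "tm1b", "lethal"),
    ("Cpsf3", "tm1b", "viable", "tm1a", "lethal"),
    ("Dbn1", "em1", "viable", "tm1b", "lethal"),
    ("Dnmt3a", "tm1a", "viable", "tm1b", "subviable"),
    ("Dppa1", "tm1a", "viable", "tm1b", "lethal"),
    ("Exoc3l2", "tm1a", "viable", "tm1b", "lethal"),
    ("Foxj3", "tm1a", "viable", "tm1b", "lethal"),
    ("Ino80", "tm1b", "viable", "tm1a", "lethal"),
    ("Itm2c", "em2", "viable", "tm1b", "lethal"),
    ("Kdm8", "tm1a", "viable", "tm1b", "lethal"),
    ("Lmna", "tm1a", "viable", "tm1b", "lethal"),
    ("Nxn", "tm1a", "viable", "tm1b", "lethal"),
    ("Rundc1", "tm1b", "viable", "tm1a", "lethal"),
    ("Slc20a2", "tm1a", "viable", "tm1b", "subviable"),
    ("Tox3", "em1", "viable", "tm1b", "lethal"),
    ("Zranb1", "tm1a", "viable", "tm1b", "lethal"),
]


@dataclass
class ConflictSummary:
    n_strains: int
    discordant_genes: List[str]
    percent: int  # nearest integer

    def as_dict(self) -> dict:
        return {
            "n_strains": self.n_strains,
            "n_discordant": len(self.discordant_genes),
            "discordant_genes": self.discordant_genes,
            "percent": self.percent,
        }


def impc_conflict_records() -> pd.DataFrame:
    """The published 17 discordant genes as a two-row-per-gene table."""
    rows = []
    for gene, a1, c1, a2, c2 in _TABLE1_ROWS:
        rows.append({"gene_symbol": gene, "allele_label": a1, "phenotype_class": c1})
        rows.append({"gene_symbol": gene, "allele_label": a2, "phenotype_class": c2})
    return pd.DataFrame(rows)


def read_viability_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_symbol", "allele_label", "phenotype_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"viability table missing column(s) {sorted(missing)}")
    bad = set(df["phenotype_class"]) - set(VIABILITY_CLASSES)
    if bad:
        raise ValueError(f"unknown phenotype class(es) {sorted(bad)}")
    return df


def write_viability_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def conflict_table(
    records: pd.DataFrame, n_strains: Optional[int] = None
) -> ConflictSummary:
    """Genes with two or more allele records of unequal viability class.

    ``n_strains`` is the census denominator; it defaults to the number of
    distinct genes in the table, but can be set to the size of the full
    cohort when the table lists only the discordant rows.
    """
    if records.empty:
        raise ValueError("empty viability table")
    dupes = records.duplicated(subset=["gene_symbol", "allele_label"])
    if dupes.any():
        dup = records.loc[dupes, ["gene_symbol", "allele_label"]].iloc[0]
        raise ValueError(
            f"duplicate allele row for {dup.gene_symbol}/{dup.allele_label}"
        )
    by_gene = records.groupby("gene_symbol", sort=False)["phenotype_class"].agg(
        lambda s: (len(s) >= 2) and (s.nunique() > 1)
    )
    discordant = sorted(by_gene.index[by_gene].tolist())
    if n_strains is None:
        n_strains = records["gene_symbol"].nunique()
    return ConflictSummary(
        n_strains=n_strains,
        discordant_genes=discordant,
        percent=round(100 * len(discordant) / n_strains),
    )
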