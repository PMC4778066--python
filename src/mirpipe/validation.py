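"""qRT-PCR relative expression, miRNA/target concordance, and GO tallies.

Relative expression follows the ddCt scheme: technical replicates of each
sample are averaged, dCt = Ct(gene) - Ct(internal standard) per biological
replicate, ddCt = dCt - mean dCt of the control condition, and relative
expression = 2^-ddCt (control mean = 1 by construction).

Concordance classifies each (miRNA fold change, target relative expression)
pair: *reverse* when the target moves against the miRNA (miRNA up and
target < 1, or miRNA down and target > 1), *same* when it moves with it
(a target exactly at 1 counts as same — no change is not a reversal), and
*not_detected* when the target gave no qRT-PCR signal.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceRecord:
    mirna_id: str
    mirna_log2fc: float
    target_id: str
    target_relative_expression: float | None   # None = not detected

    @property
    def classification(self) -> str:
        t = self.target_relative_expression
        if t is None:
            return "not_detected"
        if (self.mirna_log2fc < 0 and t > 1) or (self.mirna_log2fc > 0 and t < 1):
            return "reverse"
        if t == 1:
            logger.info("target %s relative expression exactly 1; counted as same",
                        self.target_id)
        return "same"


def ddct_relative_expression(ct: pd.DataFrame,
                             control_condition: str = "control") -> pd.DataFrame:
    """Relative expression per condition from a Ct table.

    ``ct`` columns: condition, bio_rep, tech_rep, ct_gene, ct_reference.
    Returns per condition: mean and SD of 2^-ddCt over biological replicates.
    """
    required = {"condition", "bio_rep", "tech_rep", "ct_gene", "ct_reference"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if ct["ct_reference"].isna().any():
        raise ValueError("missing reference-gene Ct")
    if control_condition not in set(ct["condition"]):
        raise ValueError(f"reference condition '{control_condition}' absent")

    by_bio = (ct.groupby(["condition", "bio_rep"])[["ct_gene", "ct_reference"]]
              .mean())
    dct = by_bio["ct_gene"] - by_bio["ct_reference"]
    control_mean = dct.loc[control_condition].mean()
    rel = 2.0 ** -(dct - control_mean)
    out = rel.groupby("condition").agg(["mean", "std"])
    out.columns = ["relative_expression", "sd"]
    return out


def concordance_counts(records: list[ConcordanceRecord]
                       ) -> tuple[int, int, int, int]:
    """(n_reverse, n_same, n_not_detected, percent_reverse-of-total)."""
    n_rev = sum(1 for r in records if r.classification == "reverse")
    n_same = sum(1 for r in records if r.classification == "same")
    n_nd = sum(1 for r in records if r.classification == "not_detected")
    total = len(records)
    pct = round(n_rev / total * 100) if total else 0
    return n_rev, n_same, n_nd, pct


def load_table2_fixture() -> list[ConcordanceRecord]:
    """The bundled transcription of the published qRT-PCR validation table:
    77 miRNA/target pairs from Mg-deficient vs -sufficient citrus leaves."""
    path = importlib.resources.files("mirpipe.data") / "table2_targets.tsv"
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        val = None if str(row.relative_change) == "ND" else float(row.relative_change)
        records.append(ConcordanceRecord(
            mirna_id=row.mirna_id,
            mirna_log2fc=float(row.mirna_log2fc),
            target_id=str(row.target_id),
            target_relative_expression=val,
        ))
    return records


GO_CATEGORIES = ("biological process", "molecular function", "cellular component")


def go_tally(targets: list[str], mapping: pd.DataFrame) -> dict[str, pd.Series]:
    """Gene counts per GO term per category for a set of target genes.

    ``mapping`` columns: gene_id, category, term.  Each gene counts once per
    distinct term; genes with no mapping are tallied under the special term
    ``unannotated`` in every category dict's companion count.
    """
    required = {"gene_id", "category", "term"}
    if required - set(mapping.columns):
        raise ValueError(f"mapping must have columns {sorted(required)}")
    bad = set(mapping["category"]) - set(GO_CATEGORIES)
    if bad:
        raise ValueError(f"unknown GO category labels: {sorted(bad)}")
    target_set = set(targets)
    sub = mapping[mapping["gene_id"].isin(target_set)].drop_duplicates(
        ["gene_id", "category", "term"])
    out: dict[str, pd.Series] = {}
    for cat in GO_CATEGORIES:
        counts = (sub[sub["category"] == cat].groupby("term")["gene_id"]
                  .nunique().sort_values(ascending=False))
        out[cat] = counts
    annotated = set(sub["gene_id"])
    out["unannotated"] = pd.Series(
        {"unannotated": len(target_set - annotated)}, dtype=int)
    return out
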