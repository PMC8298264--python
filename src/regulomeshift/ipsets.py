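"""BP coverage by interacting proteins and gene-membership partitions.

Given the biological processes annotated to the differentially expressed
gene set and the processes annotated to known interacting proteins (IPs) of
the cofactor, this module identifies the processes covered by at least one
IP versus those associated only with the cofactor itself, and partitions the
genes of a chosen process set by their membership pattern (unique to one
process, shared, present in all).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_tables import AnnotationTable, IPAnnotationTable


@dataclass
class MembershipPartition:
    """Gene membership bit-vectors over an ordered set of processes."""

    bp_set: list[str]
    membership: pd.DataFrame  # gene x bp booleans
    unique_counts: dict[str, int]  # genes annotated to exactly that one BP
    in_all: int
    total: int
    pattern_counts: dict[tuple[bool, ...], int]


def collect_ip_bps(ip_ann: IPAnnotationTable, by_name: bool = False) -> set:
    """Union of process ids (or case-folded names) across all IPs."""
    if by_name:
        return {n.casefold() for n in ip_ann.records["term_name"]}
    return set(ip_ann.records["term_id"])


def akirin2_only_bps(
    de_ann: AnnotationTable,
    ip_ann: IPAnnotationTable,
    by_name: bool = False,
) -> pd.DataFrame:
    """Coverage of the DE-gene processes by interacting proteins.

    Returns one row per distinct BP among ``de_ann`` with the set of IPs
    annotated to it, its DE-gene count, and ``akirin2_only`` true when no IP
    covers it.  Comparison is by term id; ``by_name`` switches to
    case-folded term names for sources whose tables only carry names.
    """
    ip_rec = ip_ann.records
    if by_name:
        key = lambda row: row["term_name"].casefold()  # noqa: E731
    else:
        key = lambda row: row["term_id"]  # noqa: E731
    ip_of: dict[str, set[str]] = {}
    for _, row in ip_rec.iterrows():
        ip_of.setdefault(key(row), set()).add(row["ip_id"])
    rows = []
    de = de_ann.records
    for term_id, grp in de.groupby("term_id", sort=True):
        k = grp.iloc[0]["term_name"].casefold() if by_name else term_id
        covering = ip_of.get(k, set())
        rows.append({
            "bp_id": term_id,
            "bp_name": grp.iloc[0]["term_name"],
            "covering_ips": ",".join(sorted(covering)),
            "n_covering_ips": len(covering),
            "gene_count": grp["gene_id"].nunique(),
            "akirin2_only": len(covering) == 0,
        })
    return pd.DataFrame(
        rows, columns=["bp_id", "bp_name", "covering_ips", "n_covering_ips",
                       "gene_count", "akirin2_only"]
    )


def membership_partition(
    de_ann: AnnotationTable, bp_set: Sequence[str]
) -> MembershipPartition:
    """Partition genes of ``bp_set`` by their membership pattern.

    Every gene annotated to at least one member process gets a boolean
    vector over ``bp_set``; the summary counts genes unique to each single
    process, genes annotated to all of them, and the total (the size of the
    gene union).
    """
    bp_set = list(bp_set)
    if not bp_set:
        raise ValueError("bp_set must be non-empty")
    rec = de_ann.records
    rec = rec[rec["term_id"].isin(bp_set)]
    genes = sorted(rec["gene_id"].unique())
    member = pd.DataFrame(False, index=genes, columns=bp_set)
    for _, row in rec.iterrows():
        member.at[row["gene_id"], row["term_id"]] = True
    patterns: dict[tuple[bool, ...], int] = {}
    for g in genes:
        pat = tuple(bool(x) for x in member.loc[g])
        patterns[pat] = patterns.get(pat, 0) + 1
    unique_counts = {
        bp: patterns.get(
            tuple(b == bp for b in bp_set), 0
        )
        for bp in bp_set
    }
    in_all = patterns.get(tuple(True for _ in bp_set), 0)
    return MembershipPartition(
        bp_set=bp_set,
        membership=member,
        unique_counts=unique_counts,
        in_all=in_all,
        total=len(genes),
        pattern_counts=patterns,
    )


def partition_report(p: MembershipPartition) -> pd.DataFrame:
    """Flat TSV-ready view of a membership partition."""
    rows = [{"category": f"unique_to_{bp}", "n_genes": n}
            for bp, n in p.unique_counts.items()]
    rows.append({"category": "in_all", "n_genes": p.in_all})
    rows.append({"category": "total", "n_genes": p.total})
    return pd.DataFrame(rows)
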