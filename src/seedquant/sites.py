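"""Physicochemical residue classes and discriminative-site scanning.

A discriminative site is an alignment column whose side-chain chemistry
cleanly separates two predefined groups of sequences - for example a
column that is basic in low-seeding species but non-basic in high-seeding
ones.  Charged positions matter because side-chain charge strongly shapes
protein-protein contacts during fibril elongation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import GAP, Alignment

__all__ = ["RESIDUE_CLASSES", "CLASS_MEMBERS", "residue_property",
           "SiteReport", "discriminative_site_scan"]

# fixed five-class side-chain chemistry table
RESIDUE_CLASSES: dict[str, str] = {}
CLASS_MEMBERS: dict[str, str] = {
    "acidic": "DE",
    "basic": "KRH",
    "polar": "STNQCY",
    "hydrophobic": "AVLIMFW",
    "special": "GP",
}
for _cls, _members in CLASS_MEMBERS.items():
    for _aa in _members:
        RESIDUE_CLASSES[_aa] = _cls


def residue_property(aa: str) -> str:
    """Side-chain class of a single residue letter.

    D,E acidic; K,R,H basic; S,T,N,Q,C,Y polar; A,V,L,I,M,F,W
    hydrophobic; G,P special.
    """
    try:
        return RESIDUE_CLASSES[aa]
    except KeyError:
        raise ValueError(f"unknown residue letter {aa!r}") from None


@dataclass(frozen=True)
class SiteReport:
    """One alignment column separating two sequence groups.

    ``column`` is 1-based.  ``group_*_class`` is the group's single
    side-chain class, or None when the group is chemically mixed (only
    possible under the loose "disjoint" strictness).
    """

    column: int
    group_a_residues: tuple[str, ...]
    group_b_residues: tuple[str, ...]
    group_a_class: str | None
    group_b_class: str | None
    discriminating: bool = True


def _group_classes(residues: tuple[str, ...]) -> set[str]:
    return {residue_property(r) for r in residues}


def discriminative_site_scan(aln: Alignment, group_a: set[str],
                             group_b: set[str], strictness: str = "class"
                             ) -> list[SiteReport]:
    """Scan alignment columns for sites separating two sequence groups.

    Strictness levels:

    - ``"class"`` (default): each group is internally uniform in
      side-chain class and the two classes differ.
    - ``"residue"``: each group is uniform in residue identity (classes
      must still differ between groups).
    - ``"disjoint"``: the class *sets* of the two groups do not overlap;
      groups may be internally mixed (e.g. Gln/Ile versus Lys).

    Any gap inside either group excludes the column.  Columns are
    reported 1-based.
    """
    if strictness not in ("class", "residue", "disjoint"):
        raise ValueError(f"unknown strictness {strictness!r}")
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("groups must be non-empty")
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    missing = (group_a | group_b) - set(aln.ids)
    if missing:
        raise ValueError(f"labels not in alignment: {sorted(missing)}")

    rows_a = [aln.row(g) for g in sorted(group_a)]
    rows_b = [aln.row(g) for g in sorted(group_b)]
    reports: list[SiteReport] = []
    for k in range(aln.column_count):
        res_a = tuple(r[k] for r in rows_a)
        res_b = tuple(r[k] for r in rows_b)
        if GAP in res_a or GAP in res_b or "X" in res_a or "X" in res_b:
            continue
        cls_a, cls_b = _group_classes(res_a), _group_classes(res_b)
        if cls_a & cls_b:
            continue
        if strictness == "class" and (len(cls_a) > 1 or len(cls_b) > 1):
            continue
        if strictness == "residue" and (len(set(res_a)) > 1
                                        or len(set(res_b)) > 1):
            continue
        reports.append(SiteReport(
            column=k + 1,
            group_a_residues=res_a,
            group_b_residues=res_b,
            group_a_class=next(iter(cls_a)) if len(cls_a) == 1 else None,
            group_b_class=next(iter(cls_b)) if len(cls_b) == 1 else None,
        ))
    return reports
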