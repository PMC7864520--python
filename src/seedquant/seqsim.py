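"""Simulation of SAA-like protein sequence families.

Sequences evolve along a user-supplied rooted tree (newick, branch
lengths in expected substitutions per site) under an i.i.d. jump process:
per branch, each site receives Poisson(branch length) substitution
events, each replacing the residue with one of the other 19 uniformly.
Selected "planted" columns are held out of this process and instead carry
an exact group-discriminative side-chain pattern - emulating, e.g., a
family in which the high-seeding species carry Gln/Ile at a position
where the low-seeding species carry a basic Lys.

The generator also applies a cleanup pass: any non-planted column whose
pattern happens to separate the configured groups into disjoint
side-chain classes is re-evolved along the same tree (rejection
sampling from the substitution process conditioned on being
non-discriminative), so on generator output the planted columns are
exactly the discriminative ones - clean ground truth for the site scan -
while the background columns keep the process's divergence structure.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from Bio import Phylo

from .align import AMINO_ACIDS, SequenceRecord
from .sites import CLASS_MEMBERS, residue_property

__all__ = ["PlantedSite", "SequenceSimParams", "SequenceFamily",
           "simulate_sequence_family", "DEFAULT_TREE", "DEFAULT_GROUPS",
           "DEFAULT_PLANTED_SITES"]

# six-species ultrametric default: a close mouse-cat clade (joined by
# human) against a ruminant/camel clade, root height 0.14 subs/site
DEFAULT_TREE = ("(((mouse:0.03,cat:0.03):0.07,human:0.10):0.04,"
                "((cattle:0.08,goat:0.08):0.03,camel:0.11):0.03);")

DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "high": ("mouse", "cat"),
    "low": ("camel", "cattle", "goat"),
}


@dataclass(frozen=True)
class PlantedSite:
    """A group-discriminative column to hold fixed during simulation.

    ``assignment`` maps each group name to either a side-chain class name
    (``acidic``/``basic``/``polar``/``hydrophobic``/``special``) or an
    explicit string of allowed residues (e.g. ``"QI"``).  Each leaf in a
    group draws uniformly from the group's allowed residues.
    """

    column: int  # 1-based
    assignment: dict[str, str]

    def allowed(self, group: str) -> str:
        spec = self.assignment[group]
        if spec in CLASS_MEMBERS:
            return CLASS_MEMBERS[spec]
        if not spec or any(r not in AMINO_ACIDS for r in spec):
            raise ValueError(f"unrealizable planted assignment {spec!r}")
        return spec


# mirrors the discriminative pattern of real SAA families: position 48
# Gln/Ile (high) vs basic Lys (low); position 125 acidic (high) vs Ala
DEFAULT_PLANTED_SITES: tuple[PlantedSite, ...] = (
    PlantedSite(48, {"high": "QI", "low": "K"}),
    PlantedSite(125, {"high": "DE", "low": "A"}),
)


@dataclass(frozen=True)
class SequenceSimParams:
    ancestor_length: int = 130
    tree_spec: str = DEFAULT_TREE
    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS))
    planted_sites: tuple[PlantedSite, ...] = DEFAULT_PLANTED_SITES
    clean_background: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestor_length < 1:
            raise ValueError("ancestor_length must be >= 1")
        for site in self.planted_sites:
            if not 1 <= site.column <= self.ancestor_length:
                raise ValueError(f"planted column {site.column} out of range")
            classes_per_group = []
            for g in self.groups:
                if g not in site.assignment:
                    raise ValueError(
                        f"planted site {site.column} missing group {g!r}")
                allowed = site.allowed(g)
                classes_per_group.append({residue_property(r) for r in allowed})
            for i, ca in enumerate(classes_per_group):
                for cb in classes_per_group[i + 1:]:
                    if ca & cb:
                        raise ValueError(
                            f"planted site {site.column}: group classes "
                            "overlap; pattern is not discriminative")


@dataclass(frozen=True)
class SequenceFamily:
    """Generator output plus the ground truth that produced it."""

    records: tuple[SequenceRecord, ...]
    true_tree_newick: str
    planted_columns: tuple[int, ...]
    groups: dict[str, tuple[str, ...]]

    def record(self, species: str) -> SequenceRecord:
        return next(r for r in self.records if r.species == species)


def _mutate(seq: list[str], branch_len: float, frozen: set[int],
            rng: np.random.Generator) -> list[str]:
    if branch_len < 0:
        raise ValueError("branch lengths must be >= 0")
    out = list(seq)
    if branch_len == 0:
        return out
    n_events = rng.poisson(branch_len, len(seq))
    for i, k in enumerate(n_events):
        if i in frozen:
            continue
        for _ in range(int(k)):
            others = AMINO_ACIDS.replace(out[i], "")
            out[i] = others[int(rng.integers(len(others)))]
    return out


def simulate_sequence_family(params: SequenceSimParams) -> SequenceFamily:
    """Evolve a sequence family and return it with its ground truth.

    Deterministic for a fixed ``rng_seed``.  Leaves sharing short paths on
    the tree end up with higher pairwise identity; planted columns carry
    their exact discriminative pattern; with ``clean_background`` on, no
    other column separates the configured groups into disjoint classes.
    """
    rng = np.random.default_rng(params.rng_seed)
    tree = Phylo.read(_io.StringIO(params.tree_spec), "newick")
    frozen = {s.column - 1 for s in params.planted_sites}
    ancestor = [AMINO_ACIDS[int(i)]
                for i in rng.integers(len(AMINO_ACIDS), size=params.ancestor_length)]

    leaves: dict[str, list[str]] = {}

    def descend(clade, seq: list[str]) -> None:
        for child in clade.clades:
            bl = child.branch_length or 0.0
            child_seq = _mutate(seq, bl, frozen, rng)
            if child.is_terminal():
                leaves[child.name] = child_seq
            else:
                descend(child, child_seq)

    root = tree.root
    root_seq = _mutate(ancestor, root.branch_length or 0.0, frozen, rng)
    if root.is_terminal():  # degenerate single-leaf tree
        leaves[root.name] = root_seq
    else:
        descend(root, root_seq)

    group_of = {leaf: g for g, members in params.groups.items()
                for leaf in members}
    missing = set(group_of) - set(leaves)
    if missing:
        raise ValueError(f"group members absent from tree: {sorted(missing)}")

    # exact planted patterns (leaves outside every group keep the ancestor)
    for site in params.planted_sites:
        col = site.column - 1
        for name, seq in leaves.items():
            g = group_of.get(name)
            if g is None:
                seq[col] = ancestor[col]
            else:
                allowed = site.allowed(g)
                seq[col] = allowed[int(rng.integers(len(allowed)))]

    # cleanup: no accidental discriminative background columns.  A flagged
    # column is re-evolved from its ancestral residue along the same tree
    # until its pattern no longer separates any pair of groups into
    # disjoint classes - rejection sampling, so background columns keep the
    # process's divergence structure instead of being forced conserved.
    if params.clean_background and len(params.groups) >= 2:
        gnames = sorted(params.groups)

        def evolve_column(res: str) -> dict[str, str]:
            out: dict[str, str] = {}

            def walk(clade, r: str) -> None:
                for child in clade.clades:
                    rc = r
                    for _ in range(int(rng.poisson(child.branch_length or 0.0))):
                        others = AMINO_ACIDS.replace(rc, "")
                        rc = others[int(rng.integers(len(others)))]
                    if child.is_terminal():
                        out[child.name] = rc
                    else:
                        walk(child, rc)

            if root.is_terminal():
                out[root.name] = res
            else:
                walk(root, res)
            return out

        def separates(col_res: dict[str, str]) -> bool:
            class_sets = [
                {residue_property(col_res[m]) for m in params.groups[g]}
                for g in gnames
            ]
            return any(not (class_sets[i] & class_sets[j])
                       for i in range(len(class_sets))
                       for j in range(i + 1, len(class_sets)))

        for col in range(params.ancestor_length):
            if col in frozen:
                continue
            current = {name: seq[col] for name, seq in leaves.items()}
            while separates(current):
                current = evolve_column(ancestor[col])
            for name, seq in leaves.items():
                seq[col] = current[name]

    records = tuple(
        SequenceRecord(id=name, species=name, residues="".join(seq))
        for name, seq in sorted(leaves.items())
    )
    return SequenceFamily(
        records=records,
        true_tree_newick=params.tree_spec,
        planted_columns=tuple(sorted(s.column for s in params.planted_sites)),
        groups=dict(params.groups),
    )
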