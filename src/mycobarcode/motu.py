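"""Bootstrap-supported MOTU extraction from an nrITS2 phylogeny.

Trees are consumed, not built: the expected input is a Newick tree from a
bootstrap analysis (e.g. RAxML rapid bootstrap), with support values either
as internal node labels (``((a,b)90,(c,d)80);``) or as bracketed branch
comments (``((a,b)[90],...)``).  A MOTU is a clade of at least four tips with
bootstrap support above 75, or — where resolution fails — the
highest-supported multifurcation (polytomy) of at least six tips on a path;
nested qualifying clades are resolved to the rootmost, so MOTUs are
tip-disjoint.  Each MOTU must additionally show a consistent species
identification: the modal taxon label among its labelled tips must reach a
configurable agreement fraction (default 0.5, accommodating collections with
unidentified specimens).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from collections import Counter
from pathlib import Path
from typing import Mapping

import dendropy

__all__ = ["SupportTree", "MotuClade", "read_tree", "extract_motus", "write_motu_table"]

DEFAULT_MIN_SUPPORT = 75.0
DEFAULT_MIN_CLADE = 4  # "more than three sequences"
DEFAULT_MIN_POLYTOMY = 6  # "more than five sequences"
DEFAULT_LABEL_THRESHOLD = 0.5

_NUMERIC = re.compile(r"^\s*\[?\s*([0-9]+(?:\.[0-9]+)?)\s*\]?\s*$")


class SupportTree:
    """A phylogeny with per-clade bootstrap support values.

    Wraps a dendropy tree; each internal node gets a ``support`` attribute
    (float in [0, 100] or None when missing).
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        dupes = [t for t, c in Counter(labels).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                node.support = None
                continue
            node.support = _parse_support(node)

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def write(self, path: str | Path) -> None:
        """Write Newick with supports as internal node labels."""
        for node in self.tree.preorder_node_iter():
            if not node.is_leaf() and node.support is not None:
                node.label = f"{node.support:g}"
        self.tree.write(
            path=str(path),
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )

    def midpoint_root(self) -> None:
        self.tree.reroot_at_midpoint(update_bipartitions=True)

    def outgroup_root(self, tip: str) -> None:
        node = self.tree.find_node_with_taxon_label(tip)
        if node is None:
            raise ValueError(f"outgroup tip {tip!r} not found")
        self.tree.to_outgroup_position(node, update_bipartitions=True)


def _parse_support(node: dendropy.Node) -> float | None:
    candidates = []
    if node.label:
        candidates.append(node.label)
    candidates.extend(c for c in (node.comments or []))
    for cand in candidates:
        m = _NUMERIC.match(str(cand))
        if m:
            val = float(m.group(1))
            if not 0.0 <= val <= 100.0:
                raise ValueError(f"bootstrap support {val} outside [0, 100]")
            return val
    return None


def read_tree(newick: str | Path) -> SupportTree:
    """Read a bootstrap-annotated Newick file into a :class:`SupportTree`.

    Supports both annotation dialects (internal node labels and bracketed
    branch comments); missing supports are preserved as missing.  Malformed
    Newick or duplicate tip labels raise.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(newick),
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:
        raise ValueError(f"cannot parse Newick file {newick}: {exc}") from exc
    return SupportTree(tree)


@dataclass(frozen=True)
class MotuClade:
    """One molecular operational taxonomic unit."""

    motu_id: str
    tips: frozenset[str]
    support: float  # missing support reported as 0
    consensus_label: str
    label_agreement: float
    basis: str  # supported_clade | supported_polytomy

    def __post_init__(self) -> None:
        minimum = DEFAULT_MIN_CLADE if self.basis == "supported_clade" else DEFAULT_MIN_POLYTOMY
        if len(self.tips) < minimum:
            raise ValueError(
                f"{self.motu_id}: {len(self.tips)} tips below the {self.basis} minimum {minimum}"
            )

    @property
    def n_tips(self) -> int:
        return len(self.tips)


def _tip_taxon_label(tip_name: str, labels: Mapping[str, str] | None) -> str | None:
    if labels is not None:
        return labels.get(tip_name)
    if "|" in tip_name:
        return tip_name.split("|", 1)[1].replace("_", " ").strip() or None
    return None


def extract_motus(
    tree: SupportTree,
    min_support: float = DEFAULT_MIN_SUPPORT,
    min_clade: int = DEFAULT_MIN_CLADE,
    min_polytomy: int = DEFAULT_MIN_POLYTOMY,
    label_threshold: float = DEFAULT_LABEL_THRESHOLD,
    labels: Mapping[str, str] | None = None,
    reroot: str = "none",
) -> list[MotuClade]:
    """Extract tip-disjoint MOTUs from a support-annotated tree.

    Candidates are internal nodes with support > ``min_support`` and at
    least ``min_clade`` tips, plus multifurcating nodes with at least
    ``min_polytomy`` tips (the highest-supported such node on any nested
    path; missing support counts as 0).  Nested candidates resolve to the
    rootmost.  A kept clade must show modal-taxon-label agreement of at
    least ``label_threshold`` among its labelled tips; clades with no
    labelled tips are dropped.  Taxon labels come from ``labels`` (tip name
    -> label) or, failing that, from ``id|Genus_species`` style tip names.

    ``reroot``: "none" (default, consume the tree as given), "midpoint", or
    "outgroup:<tip>".
    """
    if reroot == "midpoint":
        tree.midpoint_root()
    elif reroot.startswith("outgroup:"):
        tree.outgroup_root(reroot.split(":", 1)[1])
    elif reroot != "none":
        raise ValueError(f"unknown reroot mode {reroot!r}")

    t = tree.tree
    tips_of: dict[dendropy.Node, list[str]] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            tips_of[node] = [node.taxon.label]
        else:
            tips_of[node] = [x for ch in node.child_nodes() for x in tips_of[ch]]

    def raw_support(node: dendropy.Node) -> float | None:
        # nodes created by rerooting carry no support annotation
        return getattr(node, "support", None)

    def eff_support(node: dendropy.Node) -> float:
        sup = raw_support(node)
        return sup if sup is not None else 0.0

    clade_cands = set()
    poly_cands = set()
    for node in t.preorder_internal_node_iter():
        n_tips = len(tips_of[node])
        sup = raw_support(node)
        if sup is not None and sup > min_support and n_tips >= min_clade:
            clade_cands.add(node)
        if len(node.child_nodes()) >= 3 and n_tips >= min_polytomy:
            poly_cands.add(node)

    # On each nested path of polytomy candidates keep only the highest
    # supported one (ties resolve rootward).
    dropped = set()
    for p in poly_cands:
        for anc in p.ancestor_iter():
            if anc in poly_cands:
                if eff_support(anc) >= eff_support(p):
                    dropped.add(p)
                else:
                    dropped.add(anc)
    poly_kept = poly_cands - dropped

    candidates = clade_cands | poly_kept
    # Rootmost-maximal: drop candidates nested inside another candidate.
    kept = [
        node
        for node in candidates
        if not any(anc in candidates for anc in node.ancestor_iter())
    ]

    motus: list[MotuClade] = []
    order = [n for n in t.preorder_internal_node_iter() if n in kept]
    k = 0
    for node in order:
        tip_names = tips_of[node]
        tip_labels = [
            lab for lab in (_tip_taxon_label(nm, labels) for nm in tip_names) if lab
        ]
        if not tip_labels:
            continue
        modal_label, modal_n = Counter(tip_labels).most_common(1)[0]
        agreement = modal_n / len(tip_labels)
        if agreement < label_threshold:
            continue
        basis = "supported_clade" if node in clade_cands else "supported_polytomy"
        k += 1
        motus.append(
            MotuClade(
                motu_id=f"MOTU_{k:02d}",
                tips=frozenset(tip_names),
                support=eff_support(node),
                consensus_label=modal_label,
                label_agreement=agreement,
                basis=basis,
            )
        )
    return motus


def write_motu_table(motus: list[MotuClade], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("motu_id\tsupport\tbasis\tconsensus_label\tagreement\tn_tips\ttips\n")
        for m in motus:
            fh.write(
                f"{m.motu_id}\t{m.support:g}\t{m.basis}\t{m.consensus_label}\t"
                f"{m.label_agreement:.3f}\t{m.n_tips}\t{','.join(sorted(m.tips))}\n"
            )
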