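"""Overrepresentation analysis and signature assembly.

Candidate genes are tested for enrichment in named gene sets with the
hypergeometric upper tail (overrepresentation only); the signature is the
intersection of the candidates with the union of the selected top pathways —
by default the estrogen-response (early + late, treated as one program) and
EMT sets. The published 24-gene MOTERA signature ships as a packaged
definition so scoring never requires rerunning the derivation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from scipy.stats import hypergeom

from .de import CandidateSet, benjamini_hochberg
from .io import GeneSetCollection

MEMBERSHIPS = ("estrogen_response", "emt", "both")

# set-name heuristics used when callers do not pass an explicit program map
_ESTROGEN_KEY = "ESTROGEN_RESPONSE"
_EMT_KEY = "EPITHELIAL_MESENCHYMAL"


@dataclass
class ORAResult:
    """Per-set overrepresentation statistics, ordered by p-value.

    ``table`` columns: set_name, overlap_count, set_size, candidate_count,
    universe_size, p_value, q_value; ``overlap_genes`` maps set name to the
    overlapping candidate genes.
    """

    table: pd.DataFrame
    overlap_genes: dict[str, list[str]]

    @property
    def set_names(self) -> list[str]:
        return list(self.table["set_name"])


@dataclass
class SignatureDefinition:
    """Ordered signature gene list with per-gene program membership."""

    name: str
    genes: list[str]
    membership: dict[str, str]
    source_sets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")
        undefined = [g for g in self.genes if g not in self.membership]
        if undefined:
            raise ValueError(f"membership undefined for genes: {undefined}")
        bad = {m for m in self.membership.values()} - set(MEMBERSHIPS)
        if bad:
            raise ValueError(f"unknown membership values: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.genes)

    def count(self, membership: str) -> int:
        return sum(1 for g in self.genes if self.membership[g] == membership)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "genes": [{"id": g, "membership": self.membership[g]} for g in self.genes],
            "source_sets": self.source_sets,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureDefinition":
        genes = [entry["id"] for entry in d["genes"]]
        membership = {entry["id"]: entry["membership"] for entry in d["genes"]}
        return cls(d["name"], genes, membership, list(d.get("source_sets", [])))

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def read_signature(path) -> SignatureDefinition:
    with open(path, encoding="utf-8") as fh:
        return SignatureDefinition.from_dict(json.load(fh))


def load_motera() -> SignatureDefinition:
    """The packaged 24-gene MOTERA signature (19 estrogen-response, 2 EMT, 3 both)."""
    ref = resources.files("motera.data").joinpath("motera_signature.json")
    return SignatureDefinition.from_dict(json.loads(ref.read_text(encoding="utf-8")))


def overrepresentation(candidates: CandidateSet, sets: GeneSetCollection) -> ORAResult:
    """Hypergeometric upper-tail enrichment of candidates in each gene set.

    For a universe of N genes of which K are in the set, and n candidates
    with k in the set, p = P(X >= k) for X ~ Hypergeom(N, K, n). q-values
    are BH-adjusted across sets; rows are ordered by p (stable).
    """
    if not sets.universe:
        raise ValueError("gene-set universe is empty")
    universe = set(sets.universe)
    in_universe = [g for g in candidates.genes if g in universe]
    dropped = len(candidates.genes) - len(in_universe)
    if dropped:
        warnings.warn(f"{dropped} candidate gene(s) outside the universe were dropped", stacklevel=2)

    N = len(universe)
    n = len(in_universe)
    rows = []
    overlap_genes: dict[str, list[str]] = {}
    for name, members in sets.sets.items():
        member_set = set(members)
        K = len(member_set)
        overlap = [g for g in in_universe if g in member_set]
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        rows.append({"set_name": name, "overlap_count": k, "set_size": K,
                     "candidate_count": n, "universe_size": N, "p_value": p})
        overlap_genes[name] = overlap
    table = pd.DataFrame(rows)
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
    table = table.sort_values("p_value", kind="stable").reset_index(drop=True)
    return ORAResult(table, overlap_genes)


def _program_of(set_name: str) -> str | None:
    if _ESTROGEN_KEY in set_name.upper():
        return "estrogen_response"
    if _EMT_KEY in set_name.upper():
        return "emt"
    return None


def assemble_signature(candidates: CandidateSet, ora: ORAResult,
                       selected_sets: list[str] | None = None,
                       program_map: dict[str, str] | None = None,
                       name: str = "derived_signature") -> SignatureDefinition:
    """Signature = candidates ∩ union of the selected pathway sets.

    By default the selected sets are the estrogen-response (early and late)
    and EMT sets found in the ORA result; membership is ``estrogen_response``,
    ``emt`` or ``both`` according to which program(s) contain the gene.
    """
    if program_map is None:
        program_map = {s: _program_of(s) for s in ora.set_names if _program_of(s)}
    if selected_sets is None:
        selected_sets = [s for s in ora.set_names if s in program_map]
    missing = [s for s in selected_sets if s not in ora.set_names]
    if missing:
        raise ValueError(f"selected sets absent from ORA result: {missing}")
    unknown = [s for s in selected_sets if s not in program_map]
    if unknown:
        raise ValueError(f"no program (estrogen_response/emt) known for sets: {unknown}")

    programs_by_gene: dict[str, set[str]] = {}
    for s in selected_sets:
        prog = program_map[s]
        for g in ora.overlap_genes[s]:
            programs_by_gene.setdefault(g, set()).add(prog)

    genes = [g for g in candidates.genes if g in programs_by_gene]
    if not genes:
        raise ValueError("assembled signature is empty: no candidate overlaps the selected sets")
    membership = {
        g: "both" if len(programs_by_gene[g]) > 1 else next(iter(programs_by_gene[g]))
        for g in genes
    }
    return SignatureDefinition(name, genes, membership, source_sets=list(selected_sets))
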