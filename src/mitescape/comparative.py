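"""Cross-species comparison of MITE family libraries.

Two families from different genomes are "related" when their best local
alignment (either strand) reaches at least 60% identity over at least 60% of
either family's own length -- a deliberately laxer criterion than the
within-genome 80-80-80 rule, since inter-specific family pairs have diverged
far longer. The either-direction disjunction makes the relation symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import pandas as pd

from . import align

MIN_IDENTITY = 60.0
MIN_COVERAGE = 0.60


@dataclass(frozen=True)
class FamilyMatch:
    family_a: str
    family_b: str
    identity: float
    coverage_a: float  # aligned fraction of family A's length
    coverage_b: float
    related: bool

    @property
    def score_ratio(self) -> float:
        """identity/100 x best coverage; proxy used for similarity binning."""
        return self.identity / 100.0 * max(self.coverage_a, self.coverage_b)

    @property
    def similarity_bin(self) -> str:
        r = self.score_ratio
        if r <= 0.25:
            return "<=0.25"
        if r <= 0.50:
            return "<=0.50"
        if r <= 0.75:
            return "<=0.75"
        return ">0.75"


def family_match(name_a: str, seq_a: str, name_b: str, seq_b: str,
                 min_identity: float = MIN_IDENTITY,
                 min_coverage: float = MIN_COVERAGE) -> FamilyMatch:
    """Best-local-alignment comparison of two family consensi.

    Coverage is computed against each sequence's own length; the pair is
    related if either direction passes identity >= 60% and coverage >= 60%.
    """
    best = None
    for target in (seq_b, align.revcomp(seq_b)):
        a = align.best_local_alignment(seq_a, target)
        if best is None or a.score > best.score:
            best = a
    cov_a = (best.q_end - best.q_start) / len(seq_a) if seq_a else 0.0
    cov_b = (best.t_end - best.t_start) / len(seq_b) if seq_b else 0.0
    related = (best.identity >= min_identity
               and (cov_a >= min_coverage or cov_b >= min_coverage))
    return FamilyMatch(name_a, name_b, best.identity, cov_a, cov_b, related)


def pairwise_matches(libraries: Mapping[str, Mapping[str, str]],
                     min_identity: float = MIN_IDENTITY,
                     min_coverage: float = MIN_COVERAGE) -> pd.DataFrame:
    """All cross-species family comparisons as a long table."""
    rows = []
    for sp_a, sp_b in combinations(sorted(libraries), 2):
        for fam_a, seq_a in libraries[sp_a].items():
            for fam_b, seq_b in libraries[sp_b].items():
                m = family_match(fam_a, seq_a, fam_b, seq_b,
                                 min_identity, min_coverage)
                rows.append({
                    "species_a": sp_a, "family_a": fam_a,
                    "species_b": sp_b, "family_b": fam_b,
                    "identity": m.identity, "coverage_a": m.coverage_a,
                    "coverage_b": m.coverage_b, "related": m.related,
                    "similarity_bin": m.similarity_bin})
    return pd.DataFrame(rows, columns=["species_a", "family_a", "species_b",
                                       "family_b", "identity", "coverage_a",
                                       "coverage_b", "related",
                                       "similarity_bin"])


@dataclass
class SharingSummary:
    matches: pd.DataFrame            # long pairwise table ("related" rows only)
    partners: dict[tuple[str, str], set[str]]  # (species, family) -> species set
    pair_counts: pd.DataFrame        # species x species related-family counts
    degree_counts: pd.DataFrame      # focal species x n-other-species histogram


def shared_family_network(libraries: Mapping[str, Mapping[str, str]],
                          min_identity: float = MIN_IDENTITY,
                          min_coverage: float = MIN_COVERAGE) -> SharingSummary:
    """Sharing patterns across >= 2 species.

    No transitive closure: a family is shared with a species only through a
    direct match to some family of that species.
    """
    species = sorted(libraries)
    if len(species) < 2:
        raise ValueError("need at least two species libraries")
    matches = pairwise_matches(libraries, min_identity, min_coverage)
    related = matches[matches["related"]]

    partners: dict[tuple[str, str], set[str]] = {
        (sp, fam): set() for sp in species for fam in libraries[sp]}
    pair_related: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for _, row in related.iterrows():
        a = (row["species_a"], row["family_a"])
        b = (row["species_b"], row["family_b"])
        partners[a].add(row["species_b"])
        partners[b].add(row["species_a"])
        key = (row["species_a"], row["species_b"])
        pair_related.setdefault(key, set()).update([a, b])

    pair_counts = pd.DataFrame(0, index=species, columns=species, dtype=int)
    for (sp_a, sp_b), fams in pair_related.items():
        n_a = sum(1 for sp, _ in fams if sp == sp_a)
        n_b = sum(1 for sp, _ in fams if sp == sp_b)
        pair_counts.loc[sp_a, sp_b] = n_a
        pair_counts.loc[sp_b, sp_a] = n_b

    max_deg = len(species) - 1
    degree = pd.DataFrame(0, index=species,
                          columns=list(range(1, max_deg + 1)), dtype=int)
    for (sp, _fam), others in partners.items():
        if others:
            degree.loc[sp, len(others)] += 1
    return SharingSummary(matches=related.reset_index(drop=True),
                          partners=partners, pair_counts=pair_counts,
                          degree_counts=degree)
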