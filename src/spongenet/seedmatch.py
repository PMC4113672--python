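"""6-mer seed extraction, site scanning and enrichment testing.

Watson-Crick pairing to the miRNA *seed* — nucleotides 2-7 of the
mature sequence — is the minimal determinant of target recognition, so
a transcript carries a putative miRNA-recognition element (MRE)
wherever it contains the reverse complement of the seed. mRNAs are
scanned only over their 3'UTR; lncRNAs over the whole transcript.
Scanning is exact-match, strand-agnostic by construction (transcripts
are sense-strand) and U/T-insensitive; every occurrence is reported
with a 1-based start coordinate, overlaps included, and N never
matches.

A sponge pair is *seed-supported* for a miRNA when both partners carry
at least one site. Per-miRNA enrichment of seed support among selected
high-sensitivity pairs, relative to all candidate cognate pairs, is
tested with the one-sided (upper-tail) hypergeometric test;
Benjamini-Hochberg adjusted values are reported alongside raw ones.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SequenceSet, ValidationError

logger = logging.getLogger(__name__)

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_dna(seq: str) -> str:
    """Uppercase and map U->T, giving the DNA form used for matching."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return normalize_dna(seq).translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNASeed:
    """A miRNA's 6-mer seed (mature positions 2-7) and its DNA site."""

    mirna_id: str
    mature_seq: str
    seed: str
    site: str

    def __post_init__(self) -> None:
        if len(self.seed) != 6:
            raise ValidationError(f"seed of {self.mirna_id} is not 6 nt")


def extract_seed(mirna_id: str, mature_seq: str) -> MiRNASeed:
    """Extract the seed (positions 2-7, 1-based) and its target site.

    The site is the DNA reverse complement of the seed: the exact
    subsequence a transcript must contain to harbor an MRE.
    """
    if len(mature_seq) < 7:
        raise ValidationError(
            f"mature sequence of {mirna_id!r} is shorter than 7 nt "
            f"({len(mature_seq)} nt); cannot extract positions 2-7"
        )
    seed = mature_seq.upper().replace("T", "U")[1:7]
    return MiRNASeed(mirna_id, mature_seq.upper(), seed, reverse_complement(seed))


def seeds_from_sequences(seqs: SequenceSet) -> list[MiRNASeed]:
    if seqs.role != "mature_mirna":
        raise ValidationError("expected sequences with role 'mature_mirna'")
    return [extract_seed(rid, seq) for rid, seq in seqs.records.items()]


def seed_families(seeds) -> dict[str, set[str]]:
    """Partition miRNA ids by exact seed identity; keys are the seeds."""
    families: dict[str, set[str]] = defaultdict(set)
    for s in seeds:
        families[s.seed].add(s.mirna_id)
    return dict(families)


def find_sites(sequence: str, site: str) -> list[int]:
    """All (overlapping) 1-based start positions of *site* in *sequence*."""
    haystack = normalize_dna(sequence)
    needle = normalize_dna(site)
    positions = []
    start = haystack.find(needle)
    while start != -1:
        positions.append(start + 1)
        start = haystack.find(needle, start + 1)
    return positions


def scan_sites(seed: MiRNASeed, seqs: SequenceSet) -> dict[str, list[int]]:
    """Scan every transcript of *seqs* for the seed's site.

    Returns transcript_id -> strictly increasing 1-based positions;
    transcripts without a site map to an empty list.
    """
    if seqs.role not in ("utr3", "lnc_transcript"):
        raise ValidationError(f"cannot scan sequences with role {seqs.role!r}")
    return {rid: find_sites(seq, seed.site) for rid, seq in seqs.records.items()}


class SeedIndex:
    """Per-(transcript, miRNA) site positions over the scanned sequence sets."""

    def __init__(self) -> None:
        self._positions: dict[tuple[str, str], list[int]] = {}
        self._roles: dict[str, str] = {}

    @property
    def transcript_ids(self) -> set[str]:
        return set(self._roles)

    def add(self, transcript_id: str, role: str, mirna_id: str, positions) -> None:
        self._roles[transcript_id] = role
        if positions:
            self._positions[(transcript_id, mirna_id)] = sorted(positions)

    def covers(self, transcript_id: str) -> bool:
        return transcript_id in self._roles

    def positions(self, transcript_id: str, mirna_id: str) -> list[int]:
        return self._positions.get((transcript_id, mirna_id), [])

    def has_site(self, transcript_id: str, mirna_id: str) -> bool:
        return (transcript_id, mirna_id) in self._positions

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (tid, self._roles[tid], mid, pos)
            for (tid, mid), positions in sorted(self._positions.items())
            for pos in positions
        ]
        return pd.DataFrame(rows, columns=["transcript_id", "role", "mirna", "position"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, roles: dict[str, str] | None = None) -> "SeedIndex":
        index = cls()
        if roles:
            for tid, role in roles.items():
                index._roles[tid] = role
        for (tid, role, mid), grp in frame.groupby(
            ["transcript_id", "role", "mirna"], sort=False
        ):
            index.add(tid, role, mid, [int(p) for p in grp["position"]])
        return index


def build_seed_index(seeds, *sequence_sets: SequenceSet) -> SeedIndex:
    """Scan every seed against every given sequence set."""
    index = SeedIndex()
    for seqs in sequence_sets:
        for rid in seqs.records:
            index._roles[rid] = seqs.role
        for seed in seeds:
            for rid, positions in scan_sites(seed, seqs).items():
                if positions:
                    index.add(rid, seqs.role, seed.mirna_id, positions)
    return index


def pair_has_support(
    mrna_id: str, lncrna_id: str, mirna_id: str, index: SeedIndex
) -> bool:
    """True iff both the mRNA 3'UTR and the lncRNA transcript carry >= 1 site.

    A partner whose sequence was never scanned counts as unsupported
    (logged as a warning), never as an error.
    """
    for tid in (mrna_id, lncrna_id):
        if not index.covers(tid):
            logger.warning("no scanned sequence for %r; pair treated as unsupported", tid)
            return False
    return index.has_site(mrna_id, mirna_id) and index.has_site(lncrna_id, mirna_id)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Drawing *n* items without replacement from a population of *N*
    containing *K* successes; *k* observed successes in the sample.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    mirna_id: str
    k: int  # selected pairs with dual seed support
    K: int  # universe pairs with dual seed support
    n: int  # selected pairs
    N: int  # universe pairs
    p: float  # upper-tail hypergeometric p (NaN when n == 0)


def enrichment_test(
    mirna_id: str,
    selected_pairs,
    universe_pairs,
    index: SeedIndex,
) -> EnrichmentResult:
    """Seed-support enrichment of selected pairs for one miRNA.

    *universe_pairs* are all candidate (mrna, lncrna) cognate pairs,
    *selected_pairs* (a subset) those with high sensitivity for this
    miRNA. An empty selection yields an undefined (NaN) p-value.
    """
    universe = list(dict.fromkeys(universe_pairs))
    selected = list(dict.fromkeys(selected_pairs))
    universe_set = set(universe)
    if not set(selected) <= universe_set:
        raise ValidationError("selected pairs must be a subset of the universe")
    support = {
        pair: pair_has_support(pair[0], pair[1], mirna_id, index) for pair in universe
    }
    N = len(universe)
    K = sum(support.values())
    n = len(selected)
    k = sum(support[pair] for pair in selected)
    p = hypergeom_pvalue(k, K, n, N) if n > 0 else float("nan")
    return EnrichmentResult(mirna_id, k, K, n, N, p)


def enrichment_table(
    selection_frame: pd.DataFrame,
    universe_pairs,
    index: SeedIndex,
    mirna_ids=None,
) -> pd.DataFrame:
    """Per-miRNA enrichment over the selected triplet table.

    Tests each miRNA appearing in *selection_frame* (or the explicit
    *mirna_ids*) and adds Benjamini-Hochberg adjusted p-values.
    """
    if mirna_ids is None:
        mirna_ids = sorted(set(selection_frame["mirna"]))
    rows = []
    for mid in mirna_ids:
        sub = selection_frame[selection_frame["mirna"] == mid]
        selected = list(zip(sub["mrna"], sub["lncrna"]))
        res = enrichment_test(mid, selected, universe_pairs, index)
        rows.append((res.mirna_id, res.N, res.K, res.n, res.k, res.p))
    table = pd.DataFrame(rows, columns=["mirna", "N", "K", "n", "k", "p_raw"])
    table["p_bh"] = np.nan
    defined = table["p_raw"].notna()
    if defined.any():
        table.loc[defined, "p_bh"] = multipletests(
            table.loc[defined, "p_raw"], method="fdr_bh"
        )[1]
    return table
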