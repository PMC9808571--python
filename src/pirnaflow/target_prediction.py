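"""piRNA-directed cleavage-site prediction and the initiator→responder network.

Model
-----
A PIWI protein loaded with an initiator (guide) piRNA cleaves a complementary
precursor transcript.  Guide positions are numbered g1..g21 from the guide's
5' end; guide position i is compared with target position ``t1 - (i - 1)``,
where ``t1`` is the 1-based target coordinate opposite g1.  A candidate
cleavage site must

(i)   pair perfectly across the seed, g2-g7;
(ii)  form at least ``min_pairs`` (default 10) additional Watson-Crick pairs
      within g8-g21; and
(iii) be able to produce the 5' end of a responder piRNA: PIWI slicing cuts
      the target between the nucleotides opposite g10 and g11, i.e. between
      target positions ``t1 - 10`` and ``t1 - 9``, so the responder's 5' end
      is ``t1 - 9``.  A site is *verified* when a sequenced piRNA from the
      target locus actually starts at that exact position.

g1 is never evaluated.  Pairing is Watson-Crick (A:U, G:C) by default; G:U
wobble can optionally be admitted within g8-g21 only, never in the seed.

Verified sites aggregate into directed edges between source (guide) genes and
target (precursor) genes: the initiator→responder network.  The reverse
direction of the analysis is the same code with the class arguments swapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import PrecursorTranscript, normalize_rna

logger = logging.getLogger(__name__)

MIN_GUIDE_NT = 21  # need g1..g21 defined

_ENC = {"A": 0, "C": 1, "G": 2, "U": 3}
# Watson-Crick complement under this encoding is 3 - code.


@dataclass
class PiRNA:
    """A distinct small-RNA species with its read support."""

    sequence: str
    source_gene: str
    counts: dict = field(default_factory=dict)  # genotype -> reads
    start: int | None = None  # 1-based 5' position on the source precursor

    def __post_init__(self) -> None:
        self.sequence = normalize_rna(self.sequence, f"piRNA from {self.source_gene}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative read count")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageSite:
    """A predicted guide-directed slice event on a precursor."""

    guide_sequence: str
    guide_gene: str
    target_id: str
    target_gene: str
    t1: int  # 1-based target position opposite guide g1
    seed_matched: bool
    pairs_8_21: int
    verified: bool = False

    @property
    def responder_5p(self) -> int:
        return self.t1 - 9

    @property
    def cleavage_bond(self) -> tuple[int, int]:
        return (self.t1 - 10, self.t1 - 9)


@dataclass
class InitiationEdge:
    """Aggregated verified sites from one source gene into one target gene."""

    source_gene: str
    target_gene: str
    n_guides: int
    sites: list[CleavageSite] = field(default_factory=list)


@dataclass(frozen=True)
class SiteParams:
    min_pairs: int = 10
    allow_wobble: bool = False
    min_guide_rpm: float = 0.0


def encode(seq: str) -> np.ndarray:
    return np.array([_ENC[c] for c in seq], dtype=np.int8)


def _seq(x) -> str:
    if isinstance(x, str):
        return normalize_rna(x)
    if isinstance(x, (PiRNA, PrecursorTranscript)):
        return x.sequence
    raise TypeError(f"cannot extract a sequence from {type(x)!r}")


def scan_pairing(
    guide_encs: np.ndarray, target_enc: np.ndarray, allow_wobble: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pairing profiles for one or more guides along one target.

    ``guide_encs`` is (n_guides, 21): the encoded first 21 nt of each guide.
    Returns ``(seed_matched, pairs_8_21)``, each of shape
    (n_guides, len(target) - 20); column s corresponds to anchor
    ``t1 = s + 21`` (1-based).
    """
    if guide_encs.ndim == 1:
        guide_encs = guide_encs[None, :]
    if guide_encs.shape[1] != MIN_GUIDE_NT:
        raise ValueError("guides must be encoded to exactly 21 nt")
    if target_enc.size < MIN_GUIDE_NT:
        n = guide_encs.shape[0]
        return (np.zeros((n, 0), dtype=bool), np.zeros((n, 0), dtype=np.int64))
    # Window column k holds target position t1 - 20 + k, which faces guide
    # position i = 21 - k: the pattern is the reversed complement encoding.
    patt = (3 - guide_encs)[:, ::-1]  # (n, 21)
    win = sliding_window_view(target_enc, MIN_GUIDE_NT)  # (L-20, 21)
    m = win[None, :, :] == patt[:, None, :]  # (n, L-20, 21)
    if allow_wobble:
        g = guide_encs[:, ::-1]  # guide base facing window column k
        wob = ((g[:, None, :] == _ENC["G"]) & (win[None, :, :] == _ENC["U"])) | (
            (g[:, None, :] == _ENC["U"]) & (win[None, :, :] == _ENC["G"])
        )
        wob[:, :, 14:] = False  # wobble admitted in g8-g21 only
        m = m | wob
    # columns 14..19 face g7..g2 (the seed); columns 0..13 face g21..g8
    seed = m[:, :, 14:20].all(axis=2)
    pairs = m[:, :, :14].sum(axis=2)
    return seed, pairs


def pair_profile(guide, target, t1: int, allow_wobble: bool = False) -> tuple[bool, int]:
    """Pairing profile of one guide at one anchor: (seed_matched, pairs_8_21)."""
    gseq = _seq(guide)
    tseq = _seq(target)
    if len(gseq) < MIN_GUIDE_NT:
        raise ValueError(f"guide shorter than {MIN_GUIDE_NT} nt")
    if not (MIN_GUIDE_NT <= t1 <= len(tseq)):
        raise ValueError(f"t1={t1} out of range [21, {len(tseq)}]")
    seed, pairs = scan_pairing(
        encode(gseq[:MIN_GUIDE_NT]), encode(tseq), allow_wobble=allow_wobble
    )
    s = t1 - MIN_GUIDE_NT
    return bool(seed[0, s]), int(pairs[0, s])


def find_sites(
    guide,
    target: PrecursorTranscript,
    params: SiteParams = SiteParams(),
) -> list[CleavageSite]:
    """Scan every anchor t1 in [21, len(target)] for candidate cleavage sites.

    Emits sites with perfect seed pairing and ``pairs_8_21 >= params.min_pairs``,
    sorted by t1 ascending.  Guides shorter than 21 nt are skipped with a
    warning (they cannot define g21) rather than raising.
    """
    gseq = _seq(guide)
    guide_gene = guide.source_gene if isinstance(guide, PiRNA) else ""
    if len(gseq) < MIN_GUIDE_NT:
        logger.warning(
            "guide %r (%d nt) shorter than %d nt; skipped",
            gseq,
            len(gseq),
            MIN_GUIDE_NT,
        )
        return []
    seed, pairs = scan_pairing(
        encode(gseq[:MIN_GUIDE_NT]), encode(target.sequence), params.allow_wobble
    )
    hits = np.nonzero(seed[0] & (pairs[0] >= params.min_pairs))[0]
    return [
        CleavageSite(
            guide_sequence=gseq,
            guide_gene=guide_gene,
            target_id=target.transcript_id,
            target_gene=target.source_gene or target.transcript_id,
            t1=int(s) + MIN_GUIDE_NT,
            seed_matched=True,
            pairs_8_21=int(pairs[0, s]),
        )
        for s in hits
    ]


def verify_responder(
    site: CleavageSite, observed_5p_ends: Mapping[str, set[int] | frozenset[int]]
) -> CleavageSite:
    """Mark a site verified iff an observed piRNA 5' end from the target gene
    equals ``site.responder_5p`` exactly (no positional tolerance)."""
    ends = observed_5p_ends.get(site.target_gene, frozenset())
    return replace(site, verified=site.responder_5p in ends)


def predict_network(
    guides: Iterable[PiRNA],
    targets: Sequence[PrecursorTranscript],
    observed_5p_ends: Mapping[str, set[int] | frozenset[int]],
    params: SiteParams = SiteParams(),
) -> tuple[list[InitiationEdge], dict]:
    """Build the initiator→responder network from class-A guides to class-B
    precursors.

    Guides are deduplicated by exact sequence (counts summed) before
    scanning.  Genes present on both sides are excluded from both and
    logged; self-edges are excluded.  Returns the edge list (sorted by
    source, target) and a summary with distinct-guide / source-gene /
    target-gene counts over verified sites.
    """
    guides = list(guides)
    source_genes = {g.source_gene for g in guides}
    target_genes = {t.source_gene or t.transcript_id for t in targets}
    overlap = source_genes & target_genes
    if overlap:
        logger.warning(
            "genes in both guide and target classes excluded: %s", sorted(overlap)
        )
        guides = [g for g in guides if g.source_gene not in overlap]
        targets = [
            t for t in targets if (t.source_gene or t.transcript_id) not in overlap
        ]

    # deduplicate guide species by exact sequence within each source gene
    dedup: dict[tuple[str, str], PiRNA] = {}
    for g in guides:
        key = (g.source_gene, g.sequence)
        if key in dedup:
            for k, v in g.counts.items():
                dedup[key].counts[k] = dedup[key].counts.get(k, 0) + v
        else:
            dedup[key] = PiRNA(g.sequence, g.source_gene, dict(g.counts), g.start)
    species = [g for g in dedup.values() if len(g) >= MIN_GUIDE_NT]

    if params.min_guide_rpm > 0:
        species = [
            g
            for g in species
            if max(g.counts.values(), default=0.0) >= params.min_guide_rpm
        ]

    edges: dict[tuple[str, str], InitiationEdge] = {}
    if species and targets:
        guide_encs = np.stack([encode(g.sequence[:MIN_GUIDE_NT]) for g in species])
        for t in targets:
            tgene = t.source_gene or t.transcript_id
            ends = observed_5p_ends.get(tgene, frozenset())
            if not ends:
                continue
            seed, pairs = scan_pairing(
                guide_encs, encode(t.sequence), params.allow_wobble
            )
            gi, si = np.nonzero(seed & (pairs >= params.min_pairs))
            for g_idx, s in zip(gi.tolist(), si.tolist()):
                g = species[g_idx]
                if g.source_gene == tgene:
                    continue  # self-edge
                t1 = s + MIN_GUIDE_NT
                if (t1 - 9) not in ends:
                    continue  # criterion (iii) unverified
                site = CleavageSite(
                    guide_sequence=g.sequence,
                    guide_gene=g.source_gene,
                    target_id=t.transcript_id,
                    target_gene=tgene,
                    t1=t1,
                    seed_matched=True,
                    pairs_8_21=int(pairs[g_idx, s]),
                    verified=True,
                )
                key = (g.source_gene, tgene)
                if key not in edges:
                    edges[key] = InitiationEdge(g.source_gene, tgene, 0, [])
                edges[key].sites.append(site)

    edge_list = []
    for key in sorted(edges):
        e = edges[key]
        e.sites.sort(key=lambda s: (s.t1, s.guide_sequence))
        e.n_guides = len({s.guide_sequence for s in e.sites})
        edge_list.append(e)

    all_sites = [s for e in edge_list for s in e.sites]
    summary = {
        "n_distinct_guides": len({s.guide_sequence for s in all_sites}),
        "n_source_genes": len({e.source_gene for e in edge_list}),
        "n_target_genes": len({e.target_gene for e in edge_list}),
        "n_edges": len(edge_list),
        "n_verified_sites": len(all_sites),
    }
    return edge_list, summary
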