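"""Amino-acid similarity search over PKS subunits.

Subunits are ranked by the bit score of an optimal Smith–Waterman local
alignment with affine gaps against the query, and each hit reports which
catalytic domains the aligned span covers, together with the architecture
signature of every module — the facts (standalone subunit, AT substrate,
active reductive cassette) that donor-module filters operate on.

The aligner is internal so the package has no external binary dependency;
raw scores are converted to BLAST-compatible bit scores with the standard
gapped Karlin–Altschul parameters for BLOSUM62 (gap open 11 / extend 1):
lambda = 0.267, K = 0.041 (Altschul et al., Nucleic Acids Res. 25:3389–3402,
1997).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import substitution_matrices

from .errors import InputError, RegistryError
from .model import ArchitectureSignature, Cluster, architecture_signature
from .registries import default_extenders

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap costs and Karlin–Altschul
    parameters. A gap of length L costs ``gap_open + L * gap_extend``
    (BLAST convention)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise InputError("gap penalties must be positive")
        if self.lam <= 0 or self.k <= 0:
            raise InputError("Karlin-Altschul parameters must be positive")


@lru_cache(maxsize=4)
def _matrix(name: str):
    return substitution_matrices.load(name)


def _check_sequence(seq: str, what: str) -> str:
    if not seq:
        raise InputError(f"{what} is empty")
    seq = seq.upper()
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise InputError(
            f"{what} contains non-protein letters {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class AlignmentSpans:
    """1-based inclusive aligned spans on query and target."""

    query_start: int
    query_end: int
    target_start: int
    target_end: int


def _dp_matrices(q: str, t: str, sub, open_cost: float, ext_cost: float):
    """Gotoh three-state local DP. H = best alignment ending at (i,j) with
    q[i-1] aligned to t[j-1] or floor 0; X = gap in target (query residue
    over gap); Y = gap in query."""
    n, m = len(q), len(t)
    hs = [[0.0] * (m + 1) for _ in range(n + 1)]
    xs = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    ys = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        hi, hprev = hs[i], hs[i - 1]
        xi, xprev = xs[i], xs[i - 1]
        yi = ys[i]
        qi = q[i - 1]
        row = {aa: float(sub[qi, aa]) for aa in PROTEIN_ALPHABET}
        for j in range(1, m + 1):
            xi[j] = max(hprev[j] - open_cost, xprev[j] - ext_cost)
            yi[j] = max(hi[j - 1] - open_cost, yi[j - 1] - ext_cost)
            best_prev = hprev[j - 1]
            if xprev[j - 1] > best_prev:
                best_prev = xprev[j - 1]
            if ys[i - 1][j - 1] > best_prev:
                best_prev = ys[i - 1][j - 1]
            h = best_prev + row[t[j - 1]]
            if xi[j] > h:
                h = xi[j]
            if yi[j] > h:
                h = yi[j]
            hi[j] = h if h > 0 else 0.0
    return hs, xs, ys


def local_align(query: str, target: str,
                scheme: ScoringScheme | None = None
                ) -> tuple[int, AlignmentSpans | None]:
    """Optimal Smith–Waterman local alignment score with affine gaps.

    Returns the raw score and the aligned spans (``None`` when the best
    score is 0, i.e. nothing aligns). Among equal-scoring end cells the
    earliest ``(query, target)`` position wins, and the traceback prefers
    substitution over gap-in-target over gap-in-query, so the reported span
    is deterministic.
    """
    scheme = scheme or ScoringScheme()
    q = _check_sequence(query, "query sequence")
    t = _check_sequence(target, "target sequence")
    sub = _matrix(scheme.matrix_name)
    open_cost = float(scheme.gap_open + scheme.gap_extend)
    ext_cost = float(scheme.gap_extend)
    hs, xs, ys = _dp_matrices(q, t, sub, open_cost, ext_cost)

    best, pos = 0.0, None
    for i in range(1, len(q) + 1):
        hi = hs[i]
        for j in range(1, len(t) + 1):
            if hi[j] > best:
                best, pos = hi[j], (i, j)
    raw = int(round(best))
    if raw <= 0 or pos is None:
        return 0, None

    # value-based traceback from the best end cell to the span start
    i, j = pos
    end_i, end_j = i, j
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if hs[i][j] == 0:
                break
            diag = max(hs[i - 1][j - 1], xs[i - 1][j - 1], ys[i - 1][j - 1])
            if abs(hs[i][j] - (diag + sub[q[i - 1], t[j - 1]])) < 1e-9:
                if hs[i - 1][j - 1] >= max(xs[i - 1][j - 1],
                                           ys[i - 1][j - 1]):
                    state = "H"
                elif xs[i - 1][j - 1] >= ys[i - 1][j - 1]:
                    state = "X"
                else:
                    state = "Y"
                i, j = i - 1, j - 1
                if state == "H" and hs[i][j] == 0:
                    break
            elif hs[i][j] == xs[i][j]:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            state = "H" if abs(xs[i][j] - (hs[i - 1][j] - open_cost)) < 1e-9 \
                else "X"
            i -= 1
        else:
            state = "H" if abs(ys[i][j] - (hs[i][j - 1] - open_cost)) < 1e-9 \
                else "Y"
            j -= 1
    spans = AlignmentSpans(query_start=i + 1, query_end=end_i,
                           target_start=j + 1, target_end=end_j)
    return raw, spans


def bit_score(raw_score: float, scheme: ScoringScheme | None = None) -> float:
    """Karlin–Altschul normalization: S' = (lambda*S - ln K) / ln 2."""
    scheme = scheme or ScoringScheme()
    if raw_score < 0:
        raise InputError("raw score must be >= 0")
    return (scheme.lam * raw_score - math.log(scheme.k)) / math.log(2)


# ---------------------------------------------------------------------------
# subunit search

@dataclass
class DomainCoverage:
    """Fraction of one domain's residues inside the aligned target span."""

    module_index: int
    domain_kind: str
    fraction: float


@dataclass
class SequenceHit:
    cluster_id: str
    subunit_name: str
    raw_score: int
    bit_score: float
    spans: AlignmentSpans | None
    covered_domains: list[DomainCoverage] = field(default_factory=list)
    signatures: dict[int, ArchitectureSignature] = field(default_factory=dict)


def search_sequences(query: str, collection: list[Cluster],
                     scheme: ScoringScheme | None = None,
                     top_k: int | None = None) -> list[SequenceHit]:
    """Align the query against every subunit in the collection and rank by
    descending bit score (ties broken by ``(cluster_id, subunit_name)``).
    Subunits with no positive-scoring local alignment are omitted."""
    scheme = scheme or ScoringScheme()
    query = _check_sequence(query, "query sequence")
    hits: list[SequenceHit] = []
    for cluster in collection:
        for su in cluster.subunits:
            if not su.sequence:
                continue
            raw, spans = local_align(query, su.sequence, scheme)
            if raw <= 0:
                continue
            hit = SequenceHit(
                cluster_id=cluster.id, subunit_name=su.name, raw_score=raw,
                bit_score=bit_score(raw, scheme), spans=spans)
            for mod in su.modules:
                hit.signatures[mod.index] = architecture_signature(mod, su)
                if spans is not None:
                    for d in mod.domains:
                        frac = _coverage(d.residue_range, spans)
                        if frac > 0:
                            hit.covered_domains.append(
                                DomainCoverage(mod.index, d.kind, frac))
            hits.append(hit)
    hits.sort(key=lambda h: (-h.bit_score, h.cluster_id, h.subunit_name))
    return hits if top_k is None else hits[:top_k]


def _coverage(residue_range: tuple[int, int] | None,
              spans: AlignmentSpans) -> float:
    if residue_range is None:
        return 0.0
    start, stop = residue_range
    overlap = (min(stop, spans.target_end)
               - max(start, spans.target_start) + 1)
    return max(0.0, overlap / (stop - start + 1))


def filter_hits(hits: list[SequenceHit],
                standalone: bool | None = None,
                at_substrate: str | None = None,
                full_cassette: bool | None = None,
                cassette: set[str] | None = None) -> list[SequenceHit]:
    """Keep hits with at least one extension module satisfying every
    requested predicate; order is preserved and the filter is idempotent.

    ``full_cassette`` requires an active KR, DH and ER; ``cassette`` requires
    the active reductive set to contain the given kinds (e.g. ``{"DH"}`` to
    find donors with an active DH). Loading modules never satisfy a filter.
    """
    if at_substrate is not None and at_substrate not in default_extenders():
        raise RegistryError(
            f"unknown extender substrate {at_substrate!r} in filter")
    required = {"KR", "DH", "ER"} if full_cassette else set(cassette or ())
    if standalone is None and at_substrate is None and not required:
        return list(hits)  # vacuous filter is the identity
    out = []
    for hit in hits:
        for idx, sig in hit.signatures.items():
            if idx == 0:
                continue
            if standalone is not None and sig.standalone != standalone:
                continue
            if at_substrate is not None and sig.at_substrate != at_substrate:
                continue
            if required and not required <= sig.cassette:
                continue
            out.append(hit)
            break
    return out
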