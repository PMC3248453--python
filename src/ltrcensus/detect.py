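"""Structural detection of LTR retrotransposons by their terminal direct
repeats, and merging of multi-predictor candidate sets.

The detector is a seed-and-extend direct-repeat finder: exact k-mer seeds
on the same strand whose separation is compatible with an element length
are chained per diagonal, extended outwards with match/mismatch scoring
(X-drop), optionally snapped to the canonical 5'-TG...CA-3' LTR termini,
and filtered on LTR length, repeat identity and element length. Candidates
from any number of predictors (this one, or externally produced BED/GFF3
interval sets) are merged with the classic deduplication rule: while any
two records overlap by more than 80% of the shorter one, drop the shorter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectorParams",
    "LTRCandidate",
    "ElementRecord",
    "find_ltr_pairs",
    "overlap_fraction",
    "merge_predictions",
]


@dataclass(frozen=True)
class DetectorParams:
    min_ltr_len: int = 100
    max_ltr_len: int = 700
    min_element_len: int = 1000
    max_element_len: int = 12000
    min_ltr_identity: float = 0.8
    seed_word_len: int = 20
    require_tg_ca: bool = False
    dedup_overlap_threshold: float = 0.8

    def __post_init__(self) -> None:
        if self.min_ltr_len > self.max_ltr_len:
            raise ValueError("min_ltr_len > max_ltr_len")
        if self.min_element_len > self.max_element_len:
            raise ValueError("min_element_len > max_element_len")
        if not 0 < self.min_ltr_identity <= 1:
            raise ValueError("min_ltr_identity must be in (0,1]")
        if not 0 < self.dedup_overlap_threshold <= 1:
            raise ValueError("dedup_overlap_threshold must be in (0,1]")


@dataclass
class LTRCandidate:
    contig: str
    start: int
    end: int
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    ltr_identity: float
    tsd: str | None = None
    motif_tg_ca: bool = False
    source: str = "ltrcensus"
    score: float = 0.0

    def __post_init__(self) -> None:
        ok = (self.start == self.ltr5_start < self.ltr5_end
              <= self.ltr3_start < self.ltr3_end == self.end)
        if not ok:
            raise ValueError("inconsistent LTR candidate coordinates")


@dataclass
class ElementRecord:
    """A merged element: the unit the downstream stages annotate."""
    contig: str
    start: int
    end: int
    element_id: str = ""
    sources: list[str] = field(default_factory=list)
    strand: str = "+"
    score: float = 0.0
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# seed-and-extend detection

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_MATCH, _MISMATCH, _XDROP = 1, -2, 12


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling integer code per k-mer start; -1 where the window contains N."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j:j + n]
        out = out * 4 + np.where(window < 0, 0, window)
        bad |= window < 0
    out[bad] = -1
    return out


def _seed_pairs(codes: np.ndarray, k: int, d_min: int, d_max: int,
                max_group: int = 64) -> list[tuple[int, int]]:
    kcodes = _kmer_codes(codes, k)
    valid = np.flatnonzero(kcodes >= 0)
    if len(valid) == 0:
        return []
    order = valid[np.argsort(kcodes[valid], kind="stable")]
    sorted_codes = kcodes[order]
    boundaries = np.flatnonzero(np.diff(sorted_codes)) + 1
    pairs: list[tuple[int, int]] = []
    start = 0
    for stop in list(boundaries) + [len(order)]:
        group = np.sort(order[start:stop])
        start = stop
        if len(group) < 2 or len(group) > max_group:
            continue
        for a_idx in range(len(group) - 1):
            i = int(group[a_idx])
            for b_idx in range(a_idx + 1, len(group)):
                j = int(group[b_idx])
                d = j - i
                if d > d_max:
                    break
                if d >= d_min:
                    pairs.append((i, d))
    return pairs


def _extend(codes: np.ndarray, i0: int, i1: int, d: int) -> tuple[int, int]:
    """X-drop ungapped extension of the matched run [i0,i1) vs [i0+d,i1+d).
    Returns the extended (start, end) on the first copy."""
    n = len(codes)
    # leftwards
    best, cur, best_pos = 0, 0, i0
    p = i0 - 1
    while p >= 0 and p + d < n and cur > best - _XDROP:
        a, b = codes[p], codes[p + d]
        cur += _MATCH if (a >= 0 and a == b) else _MISMATCH
        if cur > best:
            best, best_pos = cur, p
        p -= 1
    left = best_pos
    # rightwards
    best, cur, best_pos = 0, 0, i1
    p = i1
    while p + d < n and p < n and cur > best - _XDROP:
        a, b = codes[p], codes[p + d]
        cur += _MATCH if (a >= 0 and a == b) else _MISMATCH
        if cur > best:
            best, best_pos = cur, p + 1
        p += 1
    return left, best_pos


def _refine_boundaries(seq: str, s: int, e: int, d: int,
                       window: int = 25) -> tuple[int, int]:
    """Snap repeat boundaries to the joint LTR signature.

    Candidate start offsets are those where both repeat copies begin with
    TG; candidate end offsets where both end with CA. Among the offset
    combinations, one whose implied element span is flanked by an exact
    target-site duplication is preferred (chance TSDs in random flanks are
    rare, so this pins the boundary even when the ungapped extension
    overran into coincidentally matching flank sequence); ties go to the
    smallest trim.
    """
    limit = min(window, e - s - 4)
    starts = [off for off in range(limit)
              if seq[s + off:s + off + 2] == "TG"
              and seq[s + d + off:s + d + off + 2] == "TG"] or [0]
    ends = [off for off in range(limit)
            if seq[e - off - 2:e - off] == "CA"
            and seq[e + d - off - 2:e + d - off] == "CA"] or [0]
    best = None
    for so in starts:
        for eo in ends:
            span_start, span_end = s + so, e - eo + d
            if span_end - span_start < 4:
                continue
            has_tsd = _find_tsd(seq, span_start, span_end) is not None
            key = (not has_tsd, so + eo, so, eo)
            if best is None or key < best[0]:
                best = (key, so, eo)
    if best is None:
        return s, e
    _, so, eo = best
    return s + so, e - eo


def _identity(codes: np.ndarray, s: int, e: int, d: int) -> float:
    a, b = codes[s:e], codes[s + d:e + d]
    comparable = (a >= 0) & (b >= 0)
    if comparable.sum() == 0:
        return 0.0
    return float(((a == b) & comparable).sum() / comparable.sum())


def _find_tsd(seq: str, start: int, end: int, max_len: int = 6,
              min_len: int = 4) -> str | None:
    for t in range(max_len, min_len - 1, -1):
        if start - t >= 0 and end + t <= len(seq):
            if seq[start - t:start] == seq[end:end + t]:
                return seq[start - t:start]
    return None


def _ltr_conflict(a: LTRCandidate, b: LTRCandidate) -> bool:
    """Two candidates conflict when they claim the same LTR occurrence
    (either LTR interval overlapping by >50% of the shorter)."""
    for s0, e0 in ((a.ltr5_start, a.ltr5_end), (a.ltr3_start, a.ltr3_end)):
        for s1, e1 in ((b.ltr5_start, b.ltr5_end), (b.ltr3_start, b.ltr3_end)):
            ov = min(e0, e1) - max(s0, s1)
            if ov > 0.5 * min(e0 - s0, e1 - s1):
                return True
    return False


def _resolve_conflicts(raw: list[LTRCandidate],
                       exhaustive_limit: int = 18) -> list[LTRCandidate]:
    """Pick a non-conflicting candidate subset of maximum total score.

    Tandemly inserted copies of one family generate spurious pairs (the 3'
    LTR of one insertion with the 5' LTR of the next); such a pair
    conflicts with both flanking true candidates, so a greedy best-first
    choice can block two real elements with one artifact. Within each
    conflict-graph component the maximum-weight independent set is found
    exhaustively (components are tiny: one per tandem cluster); ties go to
    the subset with more candidates, then to TSD-flanked, leftmost ones.
    """
    raw = sorted(raw, key=lambda c: (c.start, c.end))
    n = len(raw)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if _ltr_conflict(raw[i], raw[j]):
                adj[i].add(j)
                adj[j].add(i)

    unseen = set(range(n))
    chosen: list[int] = []
    while unseen:
        comp = [unseen.pop()]
        queue = [comp[0]]
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v in unseen:
                    unseen.discard(v)
                    comp.append(v)
                    queue.append(v)
        comp.sort()
        if len(comp) == 1:
            chosen.append(comp[0])
            continue
        if len(comp) <= exhaustive_limit:
            best_key, best_set = None, []
            for mask in range(1 << len(comp)):
                members = [comp[k] for k in range(len(comp)) if mask >> k & 1]
                ok = all(b not in adj[a] for ai, a in enumerate(members)
                         for b in members[ai + 1:])
                if not ok:
                    continue
                score = sum(raw[i].score for i in members)
                tsds = sum(raw[i].tsd is not None for i in members)
                key = (score, len(members), tsds,
                       tuple(-raw[i].start for i in members))
                if best_key is None or key > best_key:
                    best_key, best_set = key, members
            chosen.extend(best_set)
        else:  # fall back to greedy for pathologically dense clusters
            order = sorted(comp, key=lambda i: (-raw[i].score,
                                                raw[i].tsd is None,
                                                raw[i].start))
            taken: list[int] = []
            for i in order:
                if all(i not in adj[j] for j in taken):
                    taken.append(i)
            chosen.extend(taken)
    return [raw[i] for i in sorted(chosen)]


def find_ltr_pairs(genome: dict[str, str],
                   params: DetectorParams = DetectorParams()) -> list[LTRCandidate]:
    """Detect candidate LTR retrotransposons in each contig.

    Candidates competing for the same LTR occurrence (e.g. the 3' LTR of
    one insertion pairing with the 5' LTR of the next copy of the same
    family) are resolved per conflict cluster by maximum total score; see
    :func:`_resolve_conflicts`.
    """
    out: list[LTRCandidate] = []
    k = params.seed_word_len
    d_min = max(k, params.min_element_len - params.max_ltr_len)
    d_max = params.max_element_len
    for contig in sorted(genome):
        seq = genome[contig].upper()
        if len(seq) < params.min_element_len:
            continue
        codes = _encode(seq)
        pairs = _seed_pairs(codes, k, d_min, d_max)
        # chain seeds per diagonal into runs
        runs: dict[int, list[list[int]]] = {}
        for i, d in sorted(pairs, key=lambda x: (x[1], x[0])):
            dr = runs.setdefault(d, [])
            if dr and i - dr[-1][1] <= params.max_ltr_len:
                dr[-1][1] = max(dr[-1][1], i + k)
            else:
                dr.append([i, i + k])

        raw: list[LTRCandidate] = []
        for d, dr in runs.items():
            for i0, i1 in dr:
                s, e = _extend(codes, i0, i1, d)
                s, e = _refine_boundaries(seq, s, e, d)
                ltr_len = e - s
                if not params.min_ltr_len <= ltr_len <= params.max_ltr_len:
                    continue
                ident = _identity(codes, s, e, d)
                if ident < params.min_ltr_identity:
                    continue
                start, end = s, e + d
                if not params.min_element_len <= end - start <= params.max_element_len:
                    continue
                motif = (seq[s:s + 2] == "TG" and seq[e - 2:e] == "CA"
                         and seq[s + d:s + d + 2] == "TG"
                         and seq[e + d - 2:e + d] == "CA")
                if params.require_tg_ca and not motif:
                    continue
                raw.append(LTRCandidate(
                    contig=contig, start=start, end=end,
                    ltr5_start=s, ltr5_end=e,
                    ltr3_start=s + d, ltr3_end=e + d,
                    ltr_identity=ident,
                    tsd=_find_tsd(seq, start, end),
                    motif_tg_ca=motif,
                    source="ltrcensus.detect",
                    score=ident * ltr_len,
                ))

        out.extend(_resolve_conflicts(raw))
    out.sort(key=lambda c: (c.contig, c.start, c.end))
    return out


# ---------------------------------------------------------------------------
# merging


def _coerce(item) -> dict:
    if isinstance(item, dict):
        d = dict(item)
        d.setdefault("source", "external")
        return d
    ltr5 = ltr3 = None
    if isinstance(item, LTRCandidate):
        ltr5 = (item.ltr5_start, item.ltr5_end)
        ltr3 = (item.ltr3_start, item.ltr3_end)
    return {"contig": item.contig, "start": item.start, "end": item.end,
            "source": getattr(item, "source", "unknown"),
            "score": getattr(item, "score", 0.0),
            "strand": getattr(item, "strand", "+"),
            "ltr5": ltr5, "ltr3": ltr3}


def overlap_fraction(a, b) -> float:
    """Fraction of the shorter interval covered by the intersection.

    ``a`` and ``b`` are (contig, start, end) triples or objects/dicts with
    those fields; intervals on different contigs overlap by 0 by contract.
    """
    def unpack(x):
        if isinstance(x, tuple):
            return x
        if isinstance(x, dict):
            return x["contig"], x["start"], x["end"]
        return x.contig, x.start, x.end

    ca, sa, ea = unpack(a)
    cb, sb, eb = unpack(b)
    if ca != cb:
        return 0.0
    if sa >= ea or sb >= eb:
        raise ValueError("degenerate interval")
    inter = min(ea, eb) - max(sa, sb)
    if inter <= 0:
        return 0.0
    return inter / min(ea - sa, eb - sb)


def merge_predictions(candidate_sets: list[list],
                      threshold: float = 0.8) -> list[ElementRecord]:
    """Merge candidate sets from several predictors and remove duplicated
    hits whose overlap exceeds ``threshold`` of the shorter record.

    Collapsing is greedy on the worst-overlapping pair first (ties by
    leftmost start); the longest member of a duplicate pair survives and
    inherits the removed member's source labels. Output is sorted by
    (contig, start) and contains no pair above the threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0,1]")
    pool = [_coerce(c) for cs in candidate_sets for c in cs]
    for rec in pool:
        src = rec["source"]
        rec["sources"] = list(src) if isinstance(src, list) else [src]

    alive = list(range(len(pool)))
    while True:
        worst = None  # (fraction, start, ia, ib)
        for ai in range(len(alive)):
            for bi in range(ai + 1, len(alive)):
                a, b = pool[alive[ai]], pool[alive[bi]]
                frac = overlap_fraction(a, b)
                if frac <= threshold:
                    continue
                key = (-frac, min(a["start"], b["start"]), a["start"], b["start"])
                if worst is None or key < worst[0]:
                    worst = (key, alive[ai], alive[bi])
        if worst is None:
            break
        _, ia, ib = worst
        a, b = pool[ia], pool[ib]
        len_a, len_b = a["end"] - a["start"], b["end"] - b["start"]
        if len_a > len_b or (len_a == len_b and a["start"] <= b["start"]):
            keep, drop = ia, ib
        else:
            keep, drop = ib, ia
        for s in pool[drop]["sources"]:
            if s not in pool[keep]["sources"]:
                pool[keep]["sources"].append(s)
        alive.remove(drop)

    merged = []
    for idx in sorted(alive, key=lambda i: (pool[i]["contig"], pool[i]["start"],
                                            pool[i]["end"])):
        rec = pool[idx]
        merged.append(ElementRecord(
            contig=rec["contig"], start=rec["start"], end=rec["end"],
            sources=rec["sources"],
            strand=rec.get("strand", "+"),
            score=rec.get("score", 0.0),
            ltr5=rec.get("ltr5"), ltr3=rec.get("ltr3"),
        ))
    for n, rec in enumerate(merged):
        rec.element_id = f"{rec.contig}:{rec.start}-{rec.end}|{n}"
    return merged
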