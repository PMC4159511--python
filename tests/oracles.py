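"""Independent brute-force reference implementations used to cross-check the
package.  Everything here is deliberately naive (dict lookups, interval
enumeration, sliding windows) and shares no code with the library paths it
validates.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP.get(b, b) for b in reversed(seq.upper()))


def oracle_pair_ape(entries: dict, triplet: str):
    """Two direct table lookups: forward triplet + reverse-strand triplet."""
    t = triplet.upper()
    if any(b not in "ACGT" for b in t):
        return None
    fwd = entries.get(t)
    rev = entries.get(oracle_revcomp(t))
    if fwd is None or rev is None:
        return None
    return fwd + rev


def oracle_profile(entries: dict, sequence: str) -> list:
    """Position-by-position APE values; None marks undetermined."""
    seq = sequence.upper()
    out = [None] * len(seq)
    for i in range(1, len(seq) - 1):
        out[i] = oracle_pair_ape(entries, seq[i - 1 : i + 2])
    return out


def oracle_find_aps_intervals(values: list, apelen: int) -> list[tuple[int, int]]:
    """Enumerate every interval and keep those passing the full run predicate.

    Returns maximal runs as (run_start, run_end).  O(L^3); use on short
    profiles only.
    """
    L = len(values)
    neg = [v is not None and v < 0 for v in values]
    hits = []
    for s in range(L):
        for e in range(s, L):
            if e - s + 1 < apelen:
                continue
            if not all(neg[s : e + 1]):
                continue
            if s > 0 and neg[s - 1]:
                continue
            if e < L - 1 and neg[e + 1]:
                continue
            hits.append((s, e))
    return hits


def oracle_find_aps_scan(values: list, apelen: int) -> list[tuple[int, int]]:
    """Linear left-to-right scan for maximal negative runs (independent of
    the library's vectorised edge detection)."""
    neg = [v is not None and v < 0 for v in values]
    hits = []
    i = 0
    while i < len(neg):
        if neg[i]:
            j = i
            while j + 1 < len(neg) and neg[j + 1]:
                j += 1
            if j - i + 1 >= apelen:
                hits.append((i, j))
            i = j + 1
        else:
            i += 1
    return hits


def oracle_find_motifs(sequence: str, motifs) -> set[tuple[int, str, str, str]]:
    """Sliding-window comparison against each motif and its reverse complement.

    Returns {(start, matched_text, orientation, source_motif)}.
    """
    seq = sequence.upper()
    found = set()
    for motif in motifs:
        m = motif.upper()
        rc = oracle_revcomp(m)
        for i in range(len(seq) - len(m) + 1):
            window = seq[i : i + len(m)]
            if window == m:
                found.add((i, m, "forward", m))
            elif window == rc:
                found.add((i, rc, "reverse_complement", m))
    return found


def oracle_find_cps(
    aps_spans: list[tuple[int, int]],
    motif_starts: list[int],
    motifgap: int,
) -> set[tuple[int, int]]:
    """All (aps_span_end, motif_start) pairings with 0 <= gap <= motifgap."""
    pairs = set()
    for _, span_end in aps_spans:
        for m in motif_starts:
            gap = m - span_end - 1
            if m > span_end and 0 <= gap <= motifgap:
                pairs.add((span_end, m))
    return pairs


def random_table_entries(rng, n_undetermined: int = 14) -> dict:
    """A random single-strand table as a plain dict (the oracle's format)."""
    trips = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    undet = set(rng.choice(64, size=n_undetermined, replace=False).tolist())
    return {
        t: float(rng.uniform(-2, 2))
        for i, t in enumerate(trips)
        if i not in undet
    }


def random_dna(rng, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))
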