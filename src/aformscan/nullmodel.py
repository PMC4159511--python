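"""Monte-Carlo compositional null for APS/CPS abundance in upstream windows.

Random windows are drawn i.i.d. at fixed nucleotide frequencies, scanned
with exactly the same semantics as :func:`aformscan.scanner.scan_region`,
and the fraction of windows containing at least one APS (resp. CPS) is
scaled to the genome's gene count.  Comparing those expectations with the
observed number of genes carrying an element upstream gives the enrichment
of the structural elements over what base composition alone would produce.

The window scan is vectorised over batches so that the million-window runs
reported for genome-scale nulls stay tractable; at any batch size the drawn
sequences, and therefore all counts, are identical to feeding the same
seeded generator through the one-sequence-at-a-time scanner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .ape import ApeTable, encode_sequence, revcomp
from .scanner import ScanConfig

#: Genome-wide base composition of the Xenopus tropicalis assembly (A, C, G, T).
XTROP_FREQUENCIES = (0.299733, 0.200318, 0.200317, 0.299632)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class NullModelResult:
    """Counts and gene-scaled expectations from one null-model run."""

    n_sequences: int
    window_length: int
    frequencies: tuple[float, float, float, float]
    windows_with_aps: int
    windows_with_cps: int
    n_genes: float
    expected_aps_genes: float
    expected_cps_genes: float
    enrichment_aps: float | None
    enrichment_cps: float | None
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _normalized_frequencies(frequencies) -> np.ndarray:
    f = np.asarray(frequencies, dtype=float)
    if f.shape != (4,):
        raise ValueError("need exactly four frequencies (A, C, G, T)")
    if (f < 0).any():
        raise ValueError("frequencies must be non-negative")
    s = f.sum()
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"frequencies must sum to 1 within 1e-6, got {s}")
    return f / s


def _draw_codes(cumfreq: np.ndarray, shape, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(shape)
    return np.searchsorted(cumfreq, u, side="right").astype(np.uint8)


def random_sequence(frequencies, length: int, rng: np.random.Generator) -> str:
    """One i.i.d. DNA string at the given (A, C, G, T) frequencies."""
    if length < 0:
        raise ValueError("length must be >= 0")
    cum = np.cumsum(_normalized_frequencies(frequencies))
    cum[-1] = 1.0
    codes = _draw_codes(cum, length, rng)
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def _motif_code_patterns(motifs) -> list[np.ndarray]:
    patterns: list[bytes] = []
    for motif in motifs:
        m = motif.upper()
        for p in (m, revcomp(m)):
            if p.encode() not in patterns:
                patterns.append(p.encode())
    return [encode_sequence(p.decode()) for p in patterns]


def _batch_flags(
    codes: np.ndarray,
    pair_vals: np.ndarray,
    pair_det: np.ndarray,
    apelen: int,
    motif_codes: list[np.ndarray],
    motifgap: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row booleans (has_aps, has_cps) for a (n, L) base-code matrix."""
    n, L = codes.shape
    neg = np.zeros((n, L), dtype=bool)
    if L >= 3:
        c = codes.astype(np.intp)
        tidx = 16 * c[:, :-2] + 4 * c[:, 1:-1] + c[:, 2:]
        neg[:, 1 : L - 1] = pair_det[tidx] & (pair_vals[tidx] < 0)
    # flatten with one padding column so runs cannot cross rows
    width = L + 1
    padded = np.zeros((n, width), dtype=np.int8)
    padded[:, :L] = neg
    flat = padded.ravel()
    d = np.diff(flat, prepend=np.int8(0))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    keep = (ends - starts) >= apelen
    rows = starts[keep] // width
    span_ends = (ends[keep] - 1) % width + 1  # run_end + 1, always <= L-1
    has_aps = np.zeros(n, dtype=bool)
    has_aps[rows] = True
    has_cps = np.zeros(n, dtype=bool)
    sub = np.flatnonzero(has_aps)
    if sub.size == 0:
        return has_aps, has_cps
    sub_index = np.full(n, -1, dtype=np.intp)
    sub_index[sub] = np.arange(sub.size)
    # positions where a motif may start and still couple to some APS
    delta = np.zeros((sub.size, L + 1), dtype=np.int32)
    for r, e in zip(rows, span_ends):
        lo = e + 1
        hi = min(e + 1 + motifgap, L - 1)
        if lo <= hi:
            si = sub_index[r]
            delta[si, lo] += 1
            delta[si, hi + 1] -= 1
    allowed = np.cumsum(delta[:, :L], axis=1) > 0
    sub_codes = codes[sub]
    motif_start = np.zeros((sub.size, L), dtype=bool)
    for pattern in motif_codes:
        k = len(pattern)
        if k > L:
            continue
        match = np.ones((sub.size, L - k + 1), dtype=bool)
        for t in range(k):
            match &= sub_codes[:, t : L - k + 1 + t] == pattern[t]
        motif_start[:, : L - k + 1] |= match
    has_cps[sub] = (allowed & motif_start).any(axis=1)
    return has_aps, has_cps


def run_null(
    config: ScanConfig,
    table: ApeTable,
    frequencies=XTROP_FREQUENCIES,
    n_sequences: int = 0,
    window_length: int | None = None,
    n_genes: float = 1.0,
    seed: int = 0,
    observed_aps_genes: float | None = None,
    observed_cps_genes: float | None = None,
    batch_size: int = 20_000,
) -> NullModelResult:
    """Estimate expected APS/CPS-positive windows under the compositional null.

    ``n_sequences`` windows of ``window_length`` bp (default
    ``config.genegap``) are drawn from a generator seeded with ``seed`` and
    scanned with ``config``'s apelen/motifs/motifgap.  A window counts once
    towards ``windows_with_aps`` (``windows_with_cps``) if it contains at
    least one APS (CPS); the fractions are scaled by ``n_genes``.  When
    observed gene counts are supplied, enrichment ratios observed/expected
    are reported as well.
    """
    if n_sequences < 0:
        raise ValueError("n_sequences must be >= 0")
    L = config.genegap if window_length is None else int(window_length)
    freqs = _normalized_frequencies(frequencies)
    cum = np.cumsum(freqs)
    cum[-1] = 1.0
    pair_vals, pair_det = table.pair_arrays()
    motif_codes = _motif_code_patterns(config.motifs)
    rng = np.random.default_rng(seed)
    windows_with_aps = 0
    windows_with_cps = 0
    remaining = n_sequences
    while remaining > 0:
        b = min(batch_size, remaining)
        codes = _draw_codes(cum, (b, L), rng)
        has_aps, has_cps = _batch_flags(
            codes, pair_vals, pair_det, config.apelen, motif_codes, config.motifgap
        )
        windows_with_aps += int(has_aps.sum())
        windows_with_cps += int(has_cps.sum())
        remaining -= b
    if n_sequences > 0:
        expected_aps = windows_with_aps / n_sequences * n_genes
        expected_cps = windows_with_cps / n_sequences * n_genes
    else:
        expected_aps = expected_cps = 0.0

    def _enrichment(observed, expected):
        if observed is None:
            return None
        if expected == 0:
            return math.inf if observed > 0 else None
        return observed / expected

    return NullModelResult(
        n_sequences=n_sequences,
        window_length=L,
        frequencies=tuple(round(float(x), 12) for x in freqs),
        windows_with_aps=windows_with_aps,
        windows_with_cps=windows_with_cps,
        n_genes=n_genes,
        expected_aps_genes=expected_aps,
        expected_cps_genes=expected_cps,
        enrichment_aps=_enrichment(observed_aps_genes, expected_aps),
        enrichment_cps=_enrichment(observed_cps_genes, expected_cps),
        seed=seed,
    )
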