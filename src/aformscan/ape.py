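"""Trinucleotide A-DNA propensity energies (APE) and per-base profiles.

The propensity of a DNA duplex to adopt the A-form helix is scored per base
pair from a trinucleotide energy table: the APE value at position ``i``
depends on the central base and its 5' and 3' neighbours, and is the sum of
the table energies of the forward-strand triplet and of the reverse-strand
triplet (the reverse complement read in its own 5'->3' direction).  Negative
values (kcal/mol) favour A-form.

Not every triplet has a known energy: 14 of the 64 carry no value at all.
Positions whose calculation touches such a triplet -- or an ambiguity code,
or a sequence end -- are *undetermined* and carry no score.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
ALL_TRIPLETS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

#: Packaged default table.  SYNTHETIC: a stand-in reconstruction, see its header.
DEFAULT_TABLE_RESOURCE = "ape_table.synthetic.tsv"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> base code (A=0 C=1 G=2 T=3), 255 for everything else
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

# triplet index -> reverse-complement triplet index, where
# index(b0 b1 b2) = 16*b0 + 4*b1 + b2
_RC_INDEX = np.array(
    [16 * (3 - (t % 4)) + 4 * (3 - (t // 4) % 4) + (3 - t // 16) for t in range(64)],
    dtype=np.intp,
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, non-ACGT kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes A=0 C=1 G=2 T=3 (255 = other)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class ApeTableFormatError(ValueError):
    """Raised when an APE table file violates the TSV dialect."""


@dataclass(frozen=True)
class ApeTable:
    """Lookup of single-strand triplet APE energies (kcal/mol).

    ``entries`` holds only the determined triplets; any triplet absent from
    it is undetermined.  Energies are per strand -- the double-strand value
    returned by :func:`pair_ape` is computed, never stored.
    """

    entries: Mapping[str, float]
    source_name: str = "unnamed"
    _pair_cache: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        clean = {}
        for trip, val in dict(self.entries).items():
            t = trip.upper()
            if len(t) != 3 or any(b not in BASES for b in t):
                raise ApeTableFormatError(f"invalid triplet key {trip!r}")
            clean[t] = float(val)
        object.__setattr__(self, "entries", clean)

    @property
    def n_determined(self) -> int:
        return len(self.entries)

    @property
    def n_undetermined(self) -> int:
        return 64 - len(self.entries)

    def value(self, triplet: str) -> float | None:
        """Single-strand energy of ``triplet``, or None if undetermined."""
        return self.entries.get(triplet.upper())

    def pair_value(self, triplet: str) -> float | None:
        """Double-strand energy: T(t) + T(revcomp(t)); None if either is missing."""
        t = triplet.upper()
        a = self.entries.get(t)
        b = self.entries.get(revcomp(t))
        if a is None or b is None:
            return None
        return a + b

    def pair_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Vector form of :meth:`pair_value`.

        Returns ``(values, determined)``, each of length 64 indexed by
        ``16*b0 + 4*b1 + b2``.  ``values`` holds the forward+reverse sum
        where determined and 0.0 elsewhere.
        """
        if self._pair_cache is None:
            single = np.zeros(64)
            det = np.zeros(64, dtype=bool)
            for trip, val in self.entries.items():
                idx = (
                    16 * BASES.index(trip[0])
                    + 4 * BASES.index(trip[1])
                    + BASES.index(trip[2])
                )
                single[idx] = val
                det[idx] = True
            pair_det = det & det[_RC_INDEX]
            pair_vals = np.where(pair_det, single + single[_RC_INDEX], 0.0)
            object.__setattr__(self, "_pair_cache", (pair_vals, pair_det))
        return self._pair_cache


@dataclass(frozen=True)
class ApeProfile:
    """Per-position double-strand APE values aligned to a sequence.

    ``values[i]`` is meaningful only where ``determined[i]`` is True;
    undetermined positions hold NaN.  Positions 0 and L-1 are always
    undetermined (no 5'/3' flank).
    """

    sequence: str
    values: np.ndarray
    determined: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.sequence) == len(self.values) == len(self.determined)):
            raise ValueError("profile arrays must align with the sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def pair_ape(table: ApeTable, triplet: str) -> float | None:
    """Double-strand APE of a triplet; None for undetermined or non-ACGT input."""
    if len(triplet) != 3:
        raise ValueError(f"need a 3-letter triplet, got {triplet!r}")
    t = triplet.upper()
    if any(b not in BASES for b in t):
        return None
    return table.pair_value(t)


def ape_profile(table: ApeTable, sequence: str) -> ApeProfile:
    """Compute the per-base APE profile of ``sequence`` under ``table``.

    Case-insensitive; every interior position ``i`` scores the triplet
    ``sequence[i-1:i+2]`` via the forward+reverse strand sum.  Ends and any
    window touching a non-ACGT letter are undetermined (they never silently
    contribute zero).
    """
    seq = sequence.upper()
    n = len(seq)
    values = np.full(n, np.nan)
    determined = np.zeros(n, dtype=bool)
    if n >= 3:
        codes = encode_sequence(seq)
        valid = codes < 4
        win_valid = valid[:-2] & valid[1:-1] & valid[2:]
        c = codes.astype(np.intp)
        idx = np.where(win_valid, 16 * c[:-2] + 4 * c[1:-1] + c[2:], 0)
        pair_vals, pair_det = table.pair_arrays()
        det = win_valid & pair_det[idx]
        determined[1:-1] = det
        values[1:-1] = np.where(det, pair_vals[idx], np.nan)
    return ApeProfile(seq, values, determined)


def load_ape_table(path: str | Path, source_name: str | None = None) -> ApeTable:
    """Load an APE table from its TSV dialect.

    Each non-comment line is ``TRIPLET<TAB>VALUE`` where VALUE is a decimal
    energy (kcal/mol, single strand) or the literal ``X`` for an explicitly
    undetermined triplet.  Triplets absent from the file are undetermined
    too.  Lines starting with ``#`` are ignored.

    Raises
    ------
    ApeTableFormatError
        On a malformed triplet, a value that is neither numeric nor ``X``,
        or a duplicate triplet with a conflicting value.  The message names
        the offending line.
    """
    path = Path(path)
    entries: dict[str, float] = {}
    explicit_undet: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ApeTableFormatError(
                    f"{path}:{lineno}: expected 'TRIPLET<TAB>VALUE', got {line!r}"
                )
            trip = parts[0].upper()
            if len(trip) != 3 or any(b not in BASES for b in trip):
                raise ApeTableFormatError(
                    f"{path}:{lineno}: invalid triplet {parts[0]!r}"
                )
            if parts[1].upper() == "X":
                val = None
            else:
                try:
                    val = float(parts[1])
                except ValueError:
                    raise ApeTableFormatError(
                        f"{path}:{lineno}: value must be a decimal or 'X', "
                        f"got {parts[1]!r}"
                    ) from None
            seen = trip in entries or trip in explicit_undet
            if seen:
                previous = entries.get(trip)  # None if previously 'X'
                if previous != val:
                    raise ApeTableFormatError(
                        f"{path}:{lineno}: duplicate triplet {trip} with "
                        f"conflicting value"
                    )
                continue
            if val is None:
                explicit_undet.add(trip)
            else:
                entries[trip] = val
    table = ApeTable(entries, source_name=source_name or path.name)
    logger.info(
        "loaded APE table %s: %d determined, %d undetermined triplets",
        table.source_name,
        table.n_determined,
        table.n_undetermined,
    )
    return table


@contextmanager
def default_table_path() -> Iterator[Path]:
    """Filesystem path of the packaged default APE table (context manager)."""
    ref = resources.files(__package__).joinpath("data", DEFAULT_TABLE_RESOURCE)
    with resources.as_file(ref) as p:
        yield p


_default_cache: ApeTable | None = None


def default_table() -> ApeTable:
    """The packaged default APE table.

    SYNTHETIC stand-in: the published per-triplet energies are not
    reproduced here; this table is reconstructed from the qualitative
    behaviour of the published scale (G/C tracts strongly A-philic, C-blocks
    tolerating a leading T, ATGC repeats weakly A-philic, A/T-rich triplets
    B-philic, 14 triplets undetermined).  The scanning engine itself is
    agnostic to the numeric values; supply your own table via
    :func:`load_ape_table` for quantitative work.
    """
    global _default_cache
    if _default_cache is None:
        with default_table_path() as p:
            _default_cache = load_ape_table(p, source_name="synthetic-default")
    return _default_cache
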