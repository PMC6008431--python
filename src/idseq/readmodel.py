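"""Read architecture, barcode panels and error-tolerant barcode lookup.

An ID-seq read carries three structured elements laid out at fixed positions:
a random unique molecular identifier (UMI, default 15 nt), an antibody-dedicated
barcode (BC1, default 10 nt) and a well/sample barcode (BC2), located relative
to a constant anchor sequence.  :class:`ReadLayout` declares that geometry;
:class:`AntibodyPanel` and :class:`PlateMap` hold the barcode-to-identity
tables, and :class:`BarcodeIndex` provides Hamming-tolerant lookup with
ambiguity rejection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

VALID_BASES = frozenset("ACGT")
#: observed-base alphabet for neighbour generation; N counts as a mismatch
OBSERVED_BASES = "ACGTN"

SEGMENT_TOKENS = ("UMI", "ANCHOR", "BC1", "BC2")

#: default anchor used by the shipped layout; a placeholder constant region,
#: configurable per run (assay-specific anchors are supplied in the run config)
DEFAULT_ANCHOR = "GTAGCGACTCAG"


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings; any non-identical pair
    of characters (including N vs. anything) counts as one mismatch."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class ReadLayout:
    """Declarative geometry of a triple-barcoded read.

    Parameters
    ----------
    anchor : str
        Constant sequence locating the structured elements.
    umi_len, bc1_len, bc2_len : int
        Element lengths in nucleotides (UMI 15 nt and antibody barcode 10 nt
        by default, matching the assay design).
    segment_order : tuple of str
        Order of segments from the 5' end; must contain UMI, BC1 and BC2
        exactly once and ANCHOR at least once.
    anchor_max_mismatch : int
        Substitutions tolerated when verifying the anchor at its position.
    """

    anchor: str = DEFAULT_ANCHOR
    umi_len: int = 15
    bc1_len: int = 10
    bc2_len: int = 10
    segment_order: tuple[str, ...] = ("UMI", "ANCHOR", "BC1", "BC2")
    anchor_max_mismatch: int = 1

    def __post_init__(self) -> None:
        if not self.anchor or not set(self.anchor) <= VALID_BASES:
            raise ValueError("anchor must be a non-empty A/C/G/T string")
        for name in ("umi_len", "bc1_len", "bc2_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.anchor_max_mismatch < 0:
            raise ValueError("anchor_max_mismatch must be >= 0")
        counts = {t: self.segment_order.count(t) for t in SEGMENT_TOKENS}
        if any(counts[t] != 1 for t in ("UMI", "BC1", "BC2")) or counts["ANCHOR"] < 1:
            raise ValueError(
                "segment_order must contain UMI, BC1, BC2 exactly once and "
                f"ANCHOR at least once, got {self.segment_order}"
            )
        if set(self.segment_order) - set(SEGMENT_TOKENS):
            raise ValueError(f"unknown segment tokens in {self.segment_order}")

    def _seg_len(self, token: str) -> int:
        return {
            "UMI": self.umi_len,
            "BC1": self.bc1_len,
            "BC2": self.bc2_len,
            "ANCHOR": len(self.anchor),
        }[token]

    @property
    def segments(self) -> list[tuple[str, int, int]]:
        """(token, start, end) for every segment, in read order."""
        out, pos = [], 0
        for token in self.segment_order:
            n = self._seg_len(token)
            out.append((token, pos, pos + n))
            pos += n
        return out

    @property
    def total_length(self) -> int:
        return sum(self._seg_len(t) for t in self.segment_order)

    def to_dict(self) -> dict:
        return {
            "anchor": self.anchor,
            "umi_len": self.umi_len,
            "bc1_len": self.bc1_len,
            "bc2_len": self.bc2_len,
            "segment_order": list(self.segment_order),
            "anchor_max_mismatch": self.anchor_max_mismatch,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReadLayout":
        d = dict(d)
        if "segment_order" in d:
            d["segment_order"] = tuple(d["segment_order"])
        return cls(**d)


def _check_barcodes(ids: list[str], barcodes: list[str], what: str) -> int:
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what} ids: {dup}")
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise ValueError(f"{what} barcodes differ in length: {sorted(lengths)}")
    for bid, bc in zip(ids, barcodes):
        if not set(bc) <= VALID_BASES:
            raise ValueError(f"{what} barcode for {bid!r} has invalid bases: {bc}")
    seen: dict[str, str] = {}
    for bid, bc in zip(ids, barcodes):
        if bc in seen:
            raise ValueError(
                f"duplicate {what} barcode {bc} shared by ids "
                f"{seen[bc]!r} and {bid!r}"
            )
        seen[bc] = bid
    return lengths.pop()


@dataclass
class AntibodyPanel:
    """Antibody id → 10-nt barcode table, with optional spike-in flags.

    Spike-in entries are counted and reported alongside antibodies but play no
    role downstream.
    """

    entries: dict[str, str]
    spike_in: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = list(self.entries)
        self.barcode_length = _check_barcodes(ids, list(self.entries.values()), "antibody")
        unknown = self.spike_in - set(ids)
        if unknown:
            raise ValueError(f"spike_in flags for unknown antibodies: {sorted(unknown)}")

    @property
    def ids(self) -> list[str]:
        return list(self.entries)

    @property
    def barcodes(self) -> dict[str, str]:
        return dict(self.entries)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "AntibodyPanel":
        """Build from a table with columns ``antibody_id``, ``barcode`` and
        optionally a truthy ``spike_in`` column."""
        required = {"antibody_id", "barcode"}
        if not required <= set(df.columns):
            raise ValueError(f"panel table needs columns {sorted(required)}")
        entries = dict(zip(df["antibody_id"].astype(str), df["barcode"].str.upper()))
        spike = set()
        if "spike_in" in df.columns:
            flag = df["spike_in"].astype(str).str.lower().isin({"1", "true", "yes"})
            spike = set(df.loc[flag.values, "antibody_id"].astype(str))
        return cls(entries=entries, spike_in=spike)


@dataclass
class PlateMap:
    """Well id → barcode plus sample covariates (treatment, replicate, batch)."""

    wells: pd.DataFrame  # index well_id; columns barcode, treatment, replicate, batch, ...

    def __post_init__(self) -> None:
        if "barcode" not in self.wells.columns:
            raise ValueError("plate map needs a 'barcode' column")
        if self.wells.index.has_duplicates:
            dup = sorted(self.wells.index[self.wells.index.duplicated()].unique())
            raise ValueError(f"duplicate well ids: {dup}")
        self.barcode_length = _check_barcodes(
            list(self.wells.index.astype(str)),
            list(self.wells["barcode"].astype(str)),
            "well",
        )

    @property
    def ids(self) -> list[str]:
        return list(self.wells.index.astype(str))

    @property
    def barcodes(self) -> dict[str, str]:
        return dict(zip(self.wells.index.astype(str), self.wells["barcode"].astype(str)))

    def covariate(self, name: str) -> pd.Series:
        if name not in self.wells.columns:
            raise KeyError(f"plate map has no covariate {name!r}")
        return self.wells[name]

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "PlateMap":
        if "well_id" in df.columns:
            df = df.set_index("well_id")
        df = df.copy()
        df["barcode"] = df["barcode"].str.upper()
        return cls(wells=df)


def _barcode_map(panel) -> dict[str, str]:
    # accept AntibodyPanel, PlateMap or a plain id -> barcode dict
    if isinstance(panel, (AntibodyPanel, PlateMap)):
        return panel.barcodes
    return dict(panel)


def validate_panel(panel, tolerance: int = 1) -> dict:
    """Validate a barcode set for unambiguous correction at ``tolerance``.

    Returns a report with the minimum pairwise Hamming distance, the closest
    pair, the required distance ``2*tolerance + 1`` and a pass/fail flag.
    Duplicate barcodes raise (naming the colliding ids) at panel construction.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    barcodes = _barcode_map(panel)
    ids = list(barcodes)
    if len(ids) < 2:
        return {
            "n_barcodes": len(ids),
            "min_distance": None,
            "closest_pair": None,
            "required_distance": 2 * tolerance + 1,
            "tolerance": tolerance,
            "passed": True,
        }
    min_d, closest = None, None
    for i, j in itertools.combinations(range(len(ids)), 2):
        d = hamming(barcodes[ids[i]], barcodes[ids[j]])
        if min_d is None or d < min_d:
            min_d, closest = d, (ids[i], ids[j])
    required = 2 * tolerance + 1
    return {
        "n_barcodes": len(ids),
        "min_distance": min_d,
        "closest_pair": closest,
        "required_distance": required,
        "tolerance": tolerance,
        "passed": min_d >= required,
    }


class BarcodeIndex:
    """Hamming-tolerant barcode lookup with ambiguity rejection.

    For ``tolerance`` 1 a precomputed single-substitution neighbour dictionary
    (over A/C/G/T/N so an N in the read counts as one mismatch) gives O(1)
    lookups; larger tolerances use an exhaustive minimum-distance scan.  A
    query matching two barcodes at the same minimal distance returns no-match.
    """

    def __init__(self, panel, tolerance: int = 1, *, validate: bool = True):
        if tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        self.barcodes = _barcode_map(panel)
        if not self.barcodes:
            raise ValueError("empty barcode panel")
        self.tolerance = tolerance
        self.barcode_length = len(next(iter(self.barcodes.values())))
        if validate and tolerance > 0:
            report = validate_panel(self.barcodes, tolerance)
            if not report["passed"]:
                raise ValueError(
                    "barcode set unsafe for correction at tolerance "
                    f"{tolerance}: min pairwise distance {report['min_distance']} < "
                    f"{report['required_distance']} (closest pair {report['closest_pair']})"
                )
        self._exact = {bc: bid for bid, bc in self.barcodes.items()}
        self._neighbors: dict[str, str | None] = {}
        if tolerance == 1:
            self._build_neighbors()

    def _build_neighbors(self) -> None:
        table: dict[str, str | None] = {}
        for bid, bc in self.barcodes.items():
            for pos in range(len(bc)):
                for base in OBSERVED_BASES:
                    if base == bc[pos]:
                        continue
                    variant = bc[:pos] + base + bc[pos + 1 :]
                    if variant in self._exact:
                        continue  # exact barcodes win at distance 0
                    if variant in table and table[variant] != bid:
                        table[variant] = None  # ambiguous at distance 1
                    else:
                        table[variant] = bid
        self._neighbors = table

    def match(self, observed: str) -> str | None:
        """Return the unique id within the tolerance, or None (no-match)."""
        if len(observed) != self.barcode_length:
            raise ValueError(
                f"observed barcode length {len(observed)} != panel length "
                f"{self.barcode_length}"
            )
        hit = self._exact.get(observed)
        if hit is not None or self.tolerance == 0:
            return hit
        if self.tolerance == 1:
            return self._neighbors.get(observed)
        return self._scan(observed)

    def _scan(self, observed: str) -> str | None:
        best_d, best_id, tied = None, None, False
        for bid, bc in self.barcodes.items():
            d = hamming(observed, bc)
            if best_d is None or d < best_d:
                best_d, best_id, tied = d, bid, False
            elif d == best_d:
                tied = True
        if best_d is None or best_d > self.tolerance or tied:
            return None
        return best_id


def match_barcode(observed: str, panel, tolerance: int = 1) -> str | None:
    """One-shot tolerant lookup of ``observed`` in a panel or plate map.

    Builds a :class:`BarcodeIndex` per call; use the index directly when
    matching many reads.  Distance validation is skipped here so ambiguity
    handling can be exercised on arbitrary panels.
    """
    return BarcodeIndex(panel, tolerance, validate=False).match(observed)
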