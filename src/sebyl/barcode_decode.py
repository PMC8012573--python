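"""Fuzzy barcode demultiplexing for pooled yeast deletion-collection screens.

Each strain in the barcoded knockout collection carries two unique 20-nt
barcodes (UPTAG and DNTAG) flanking its deletion cassette. Sequencing reads
contain one of the two tags between primer-derived adapters. This module trims
the adapters, matches the remaining tag against the barcode library by exact
Levenshtein (edit) distance, and tabulates per-sample, per-strain counts —
UPTAG and DNTAG counted separately.

Matching policy: a read is assigned to the unique library barcode at minimal
edit distance if that distance is at most ``max_diff`` (default 3); ties at
the minimal distance are discarded as ambiguous rather than split
fractionally. N bases never match anything, which is conservative.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Tuple

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "AssignStatus",
    "BarcodeLibrary",
    "CountTable",
    "DecodeConfig",
    "ReadAssignment",
    "TagClass",
    "assign_read",
    "count_barcodes",
    "trim_adapters",
]

_DNA = set("ACGT")
_DNA_N = set("ACGTN")


class TagClass(str, enum.Enum):
    """Which of the two strain barcodes a read carries."""

    UPTAG = "UPTAG"
    DNTAG = "DNTAG"


class AssignStatus(str, enum.Enum):
    ASSIGNED = "assigned"
    UNASSIGNED = "unassigned"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of matching one trimmed barcode against the library."""

    read_id: str
    strain_id: Optional[str]
    status: AssignStatus
    distance: Optional[int]


@dataclass
class BarcodeLibrary:
    """strain_id -> (uptag, dntag) dictionary used for read assignment.

    A strain may lack one of its two tags (recorded as ``None``, never as an
    empty string). Sequences are upper-case ACGT; uptags are mutually
    distinct, as are dntags.
    """

    entries: dict[str, Tuple[Optional[str], Optional[str]]]
    tag_length: int = 20

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("barcode library is empty")
        seen: dict[TagClass, set[str]] = {TagClass.UPTAG: set(), TagClass.DNTAG: set()}
        for strain, (up, dn) in self.entries.items():
            if up is None and dn is None:
                raise ValueError(f"strain {strain!r} has neither tag")
            for tag, cls in ((up, TagClass.UPTAG), (dn, TagClass.DNTAG)):
                if tag is None:
                    continue
                if not tag or not set(tag) <= _DNA:
                    raise ValueError(f"invalid barcode for {strain!r}: {tag!r}")
                if tag in seen[cls]:
                    raise ValueError(f"duplicate {cls.value} barcode {tag!r}")
                seen[cls].add(tag)

    def tags(self, tag_class: TagClass) -> dict[str, str]:
        """Strain -> barcode map for one tag class, skipping absent tags."""
        idx = 0 if tag_class is TagClass.UPTAG else 1
        return {s: t[idx] for s, t in self.entries.items() if t[idx] is not None}

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tag_length: int = 20) -> "BarcodeLibrary":
        """Build from a DataFrame with columns strain_id, uptag, dntag.

        "NA"/empty cells mark an absent tag.
        """
        entries: dict[str, Tuple[Optional[str], Optional[str]]] = {}
        for row in df.itertuples(index=False):
            strain = str(row.strain_id)
            if strain in entries:
                raise ValueError(f"duplicate strain_id {strain!r}")

            def norm(x: object) -> Optional[str]:
                if x is None or (isinstance(x, float) and np.isnan(x)):
                    return None
                s = str(x).strip().upper()
                return None if s in ("", "NA") else s

            entries[strain] = (norm(row.uptag), norm(row.dntag))
        return cls(entries, tag_length=tag_length)


@dataclass
class CountTable:
    """Non-negative strain x sample count matrix for one tag class.

    Counts are integers after decoding; the simulator's expectation mode may
    produce real-valued expected counts, so the dtype is not enforced.
    """

    strains: list[str]
    samples: list[str]
    counts: np.ndarray
    tag_class: TagClass

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.strains), len(self.samples)):
            raise ValueError("counts shape does not match labels")
        if len(set(self.strains)) != len(self.strains):
            raise ValueError("duplicate strain ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.strains, name="strain_id"),
                            columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tag_class: TagClass) -> "CountTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(), tag_class)


@dataclass
class DecodeConfig:
    """Adapters and thresholds controlling trimming and assignment.

    The two tag classes are amplified with different primer pairs, so the
    adapter pair that matches a read decides its tag class. Adapter sequences
    are experiment-specific configuration, not constants.
    """

    adapters_up: Tuple[str, str]  # (5' adapter, 3' adapter) for UPTAG reads
    adapters_dn: Tuple[str, str]
    max_diff: int = 3
    adapter_mismatches: int = 1
    tag_length: int = 20

    def adapters(self, tag_class: TagClass) -> Tuple[str, str]:
        return self.adapters_up if tag_class is TagClass.UPTAG else self.adapters_dn


def _find_approx(read: str, adapter: str, max_mismatch: int, start: int = 0) -> int:
    """Index of first occurrence of adapter in read with <= max_mismatch
    substitutions (no indels: adapters are primer-derived, high fidelity).
    Returns -1 if absent. N in the read mismatches every adapter base."""
    la = len(adapter)
    for i in range(start, len(read) - la + 1):
        mm = 0
        for a, b in zip(read[i:i + la], adapter):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        if mm <= max_mismatch:
            return i
    return -1


def trim_adapters(read: str, adapter5: str, adapter3: str,
                  tag_length: int = 20, adapter_mismatches: int = 1) -> str:
    """Extract the barcode between the 5' and 3' adapters.

    Returns the subsequence between the first (approximate) occurrence of
    ``adapter5`` and the following occurrence of ``adapter3``. If ``adapter5``
    is absent the read is rejected (empty string). If ``adapter3`` is absent,
    everything after ``adapter5`` is returned, truncated to ``tag_length``.

    Raises ``ValueError`` for reads containing non-ACGTN characters, which
    callers count as malformed.
    """
    if not adapter5 or not adapter3:
        raise ValueError("adapters must be non-empty")
    read = read.upper()
    if not set(read) <= _DNA_N:
        raise ValueError("read contains non-ACGTN characters")
    i5 = _find_approx(read, adapter5, adapter_mismatches)
    if i5 < 0:
        return ""
    tag_start = i5 + len(adapter5)
    # anchor the 3' adapter at the expected tag end first so that barcodes
    # ending in near-adapter sequence are not truncated; fall back to a scan
    # (tolerates tag-length drift from indels)
    expected = tag_start + tag_length
    if expected + len(adapter3) <= len(read) and \
            _find_approx(read, adapter3, adapter_mismatches, start=expected) == expected:
        i3 = expected
    else:
        i3 = _find_approx(read, adapter3, adapter_mismatches, start=tag_start)
    if i3 < 0:
        return read[tag_start:tag_start + tag_length]
    return read[tag_start:i3]


def assign_read(barcode: str, library: BarcodeLibrary, tag_class: TagClass,
                max_diff: int = 3, read_id: str = "") -> ReadAssignment:
    """Match a trimmed barcode against the library by edit distance.

    Edit distance counts substitutions, insertions and deletions. The read is
    assigned to the unique library barcode at minimal distance <= ``max_diff``,
    marked ambiguous if two or more barcodes tie at that minimal distance, and
    unassigned otherwise. Independent of library iteration order.
    """
    if not barcode:
        raise ValueError("empty barcode")
    if max_diff < 0:
        raise ValueError("max_diff must be >= 0")
    tags = library.tags(tag_class)
    if not tags:
        raise ValueError(f"library has no {tag_class.value} barcodes")
    barcode = barcode.upper()
    best: Optional[int] = None
    best_strain: Optional[str] = None
    tied = False
    for strain, tag in tags.items():
        # N never matches: edlib treats letters literally, so N in the read
        # mismatches A/C/G/T as required.
        d = edlib.align(barcode, tag, task="distance", k=max_diff)["editDistance"]
        if d < 0:  # beyond k
            continue
        if best is None or d < best:
            best, best_strain, tied = d, strain, False
        elif d == best:
            tied = True
    if best is None:
        return ReadAssignment(read_id, None, AssignStatus.UNASSIGNED, None)
    if tied:
        return ReadAssignment(read_id, None, AssignStatus.AMBIGUOUS, best)
    return ReadAssignment(read_id, best_strain, AssignStatus.ASSIGNED, best)


def count_barcodes(
    reads_by_sample: Mapping[str, Iterable[Tuple[str, str]]],
    library: BarcodeLibrary,
    config: DecodeConfig,
) -> Tuple[CountTable, CountTable, pd.DataFrame]:
    """Decode all samples into UPTAG and DNTAG count tables plus a report.

    Parameters
    ----------
    reads_by_sample
        sample_id -> iterable of ``(read_id, sequence)`` pairs (e.g. from
        :func:`sebyl.cli_io.iter_fastq`).
    library, config
        Barcode library and decoding configuration.

    Returns
    -------
    (uptag_table, dntag_table, report)
        Count tables over all samples and the full strain list, and a
        per-sample tally DataFrame with columns total, assigned, unassigned,
        ambiguous, malformed. Ambiguous and unassigned reads contribute to no
        strain; per sample, assigned + unassigned + ambiguous + malformed
        equals the total read count.
    """
    strains = list(library.entries)
    samples = list(reads_by_sample)
    strain_idx = {s: i for i, s in enumerate(strains)}
    counts = {tc: np.zeros((len(strains), len(samples)), dtype=np.int64)
              for tc in TagClass}
    tallies = []
    min_len = config.tag_length - config.max_diff
    for j, sample in enumerate(samples):
        tally = {"sample_id": sample, "total": 0, "assigned": 0,
                 "unassigned": 0, "ambiguous": 0, "malformed": 0}
        for read_id, seq in reads_by_sample[sample]:
            tally["total"] += 1
            hit = None
            malformed = False
            for tc in TagClass:
                a5, a3 = config.adapters(tc)
                try:
                    tag = trim_adapters(seq, a5, a3, config.tag_length,
                                        config.adapter_mismatches)
                except ValueError:
                    malformed = True
                    break
                if tag:
                    hit = (tc, tag)
                    break
            if malformed:
                tally["malformed"] += 1
                continue
            if hit is None:  # no 5' adapter of either class
                tally["unassigned"] += 1
                continue
            tc, tag = hit
            if len(tag) < min_len:  # too short to match meaningfully
                tally["malformed"] += 1
                continue
            asg = assign_read(tag, library, tc, config.max_diff, read_id)
            if asg.status is AssignStatus.ASSIGNED:
                counts[tc][strain_idx[asg.strain_id], j] += 1
                tally["assigned"] += 1
            else:
                tally[asg.status.value] += 1
        tallies.append(tally)
    report = pd.DataFrame(tallies).set_index("sample_id")
    return (
        CountTable(strains, samples, counts[TagClass.UPTAG], TagClass.UPTAG),
        CountTable(strains, samples, counts[TagClass.DNTAG], TagClass.DNTAG),
        report,
    )
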