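"""Core variant representation, type classification and normalization.

Coordinates are 0-based, half-open throughout: an SNV at reference base
``p`` spans ``[p, p+1)`` and an insertion between bases is a zero-length
anchor ``[p, p)``.  Empty alleles are genuine empty strings (rendered as
``-`` in tab-separated output).  A variant's identity for all downstream
set algebra is its :func:`variant_key` — ``(chrom, start, end, ref, alt)``
taken *after* normalization, so that tumor/node/normal matching is
independent of how a caller chose to spell an indel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple, Optional

__all__ = [
    "VariantType",
    "CallStatus",
    "SampleRole",
    "GenomicInterval",
    "VariantCall",
    "VariantKey",
    "SampleVariantSet",
    "ReferenceWindow",
    "classify_variant_type",
    "normalize_variant",
    "variant_key",
    "InvalidVariantError",
    "ReferenceCallError",
    "ReferenceInconsistencyError",
    "ContractViolationError",
]


class InvalidVariantError(ValueError):
    """Both alleles empty — no variant is described."""


class ReferenceCallError(ValueError):
    """Identical non-empty alleles — a reference call, not a variant."""


class ReferenceInconsistencyError(ValueError):
    """Supplied reference sequence disagrees with the call's ref allele."""


class ContractViolationError(RuntimeError):
    """An operation was invoked outside its stated contract."""


class VariantType(str, enum.Enum):
    SNV = "snv"
    INS = "ins"
    DEL = "del"
    SUB = "sub"


class CallStatus(str, enum.Enum):
    CALLED = "called"
    NO_CALL = "no_call"
    HALF_CALL = "half_call"


class SampleRole(str, enum.Enum):
    NORMAL = "normal"
    TUMOR = "tumor"
    NODE = "node"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a chromosome.

    ``end == start`` is permitted only for insertions (a zero-length anchor
    between two reference bases).
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start: {self}")
        if self.start < 0:
            raise ValueError(f"negative start: {self}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        if self.chrom != other.chrom:
            return False
        if len(self) == 0:  # insertion anchor: strictly inside counts
            return other.start < self.start < other.end
        if len(other) == 0:
            return self.start < other.start < self.end
        return self.start < other.end and other.start < self.end

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


class VariantKey(NamedTuple):
    """Identity of a normalized variant; equal keys mean the same variant."""

    chrom: str
    start: int
    end: int
    ref: str
    alt: str


def classify_variant_type(ref_allele: str, alt_allele: str) -> VariantType:
    """Classify a ref→alt replacement as SNV, insertion, deletion or substitution.

    A substitution is any replacement with both alleles non-empty that is not
    a single-base SNV, including unequal-length block replacements.

    Raises
    ------
    InvalidVariantError
        If both alleles are empty.
    ReferenceCallError
        If the alleles are identical (non-empty) — a reference call.
    """
    if not ref_allele and not alt_allele:
        raise InvalidVariantError("both alleles empty")
    if ref_allele == alt_allele:
        raise ReferenceCallError(f"identical alleles {ref_allele!r}: not a variant")
    if not ref_allele:
        return VariantType.INS
    if not alt_allele:
        return VariantType.DEL
    if len(ref_allele) == 1 and len(alt_allele) == 1:
        return VariantType.SNV
    return VariantType.SUB


@dataclass
class VariantCall:
    """One variant observation in one sample, with read-level evidence.

    ``position_read_depth`` is the total number of reads covering the locus;
    ``alt_read_count`` the number supporting the variant allele.  The
    ``normalized`` flag is set by :func:`normalize_variant` (or by readers
    that guarantee canonical form) and is a precondition of
    :func:`variant_key`.
    """

    interval: GenomicInterval
    vtype: VariantType
    ref_allele: str
    alt_allele: str
    position_read_depth: int = 0
    alt_read_count: int = 0
    call_status: CallStatus = CallStatus.CALLED
    catalog_ids: set[str] = field(default_factory=set)
    gene_hint: Optional[str] = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.alt_read_count > self.position_read_depth:
            raise ValueError(
                f"alt_read_count {self.alt_read_count} exceeds depth "
                f"{self.position_read_depth}"
            )
        expected = classify_variant_type(self.ref_allele, self.alt_allele)
        if self.vtype != expected:
            raise ValueError(
                f"declared type {self.vtype.value} inconsistent with alleles "
                f"{self.ref_allele!r}>{self.alt_allele!r} (expect {expected.value})"
            )
        if len(self.ref_allele) != len(self.interval):
            raise ValueError(
                f"ref allele length {len(self.ref_allele)} does not match "
                f"interval span {len(self.interval)}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def key(self) -> VariantKey:
        return variant_key(self)


def variant_key(call: VariantCall) -> VariantKey:
    """Identity key ``(chrom, start, end, ref, alt)`` of a normalized call."""
    if not call.normalized:
        raise ContractViolationError(
            "variant_key requires a normalized call; run normalize_variant first"
        )
    return VariantKey(
        call.interval.chrom,
        call.interval.start,
        call.interval.end,
        call.ref_allele,
        call.alt_allele,
    )


@dataclass(frozen=True)
class ReferenceWindow:
    """A slice of reference sequence anchored at a 0-based offset."""

    chrom: str
    offset: int
    seq: str

    @property
    def end(self) -> int:
        return self.offset + len(self.seq)

    def base(self, pos: int) -> str:
        if not (self.offset <= pos < self.end):
            raise IndexError(f"position {pos} outside window [{self.offset},{self.end})")
        return self.seq[pos - self.offset]

    def slice(self, start: int, end: int) -> str:
        if start < self.offset or end > self.end or start > end:
            raise IndexError(f"[{start},{end}) outside window [{self.offset},{self.end})")
        return self.seq[start - self.offset : end - self.offset]

    def covers(self, start: int, end: int) -> bool:
        return self.offset <= start and end <= self.end


def _trim_shared(start: int, ref: str, alt: str) -> tuple[int, str, str]:
    # suffix first so prefix trimming fixes the final start coordinate
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        start += 1
    return start, ref, alt


def normalize_variant(call: VariantCall, window: ReferenceWindow) -> VariantCall:
    """Return the canonical (trimmed, left-aligned) representation of a call.

    Shared prefix/suffix bases are removed from both alleles, and pure
    indels are shifted left while the shifted spelling describes the same
    alternate haplotype (the usual left-alignment fixed point).  The result
    is idempotent: normalizing twice equals normalizing once.

    Parameters
    ----------
    call
        The variant to canonicalize.
    window
        Reference sequence covering the call's interval plus left context
        (≥50 bp recommended so runs can be traversed).

    Raises
    ------
    ReferenceInconsistencyError
        If the window's bases disagree with ``call.ref_allele``.
    """
    iv = call.interval
    if window.chrom != iv.chrom:
        raise ReferenceInconsistencyError(
            f"window on {window.chrom} cannot anchor call on {iv.chrom}"
        )
    if not window.covers(iv.start, iv.end):
        raise ReferenceInconsistencyError("reference window does not cover the call")
    if window.slice(iv.start, iv.end) != call.ref_allele:
        raise ReferenceInconsistencyError(
            f"reference at {iv.chrom}:{iv.start} is "
            f"{window.slice(iv.start, iv.end)!r}, call says {call.ref_allele!r}"
        )

    start, ref, alt = _trim_shared(iv.start, call.ref_allele, call.alt_allele)
    if not ref and not alt:
        raise ReferenceCallError("alleles identical after trimming: a reference call")

    # left-align pure indels: rotate the inserted/deleted sequence through
    # the preceding reference bases while the haplotype is unchanged
    if not ref or not alt:
        moving = alt if not ref else ref
        end = start + len(ref)
        while start > window.offset and window.base(start - 1) == moving[-1]:
            moving = window.base(start - 1) + moving[:-1]
            start -= 1
            end -= 1
        if not ref:
            alt = moving
        else:
            ref = moving
            # deleted sequence must still match the reference
            end = start + len(ref)

    end = start + len(ref)
    vtype = classify_variant_type(ref, alt)
    return replace(
        call,
        interval=GenomicInterval(iv.chrom, start, end),
        vtype=vtype,
        ref_allele=ref,
        alt_allele=alt,
        normalized=True,
    )


def spell_haplotype(window: ReferenceWindow, call: VariantCall) -> str:
    """Alternate haplotype spelled over the whole window — the oracle used to
    prove two representations of a variant are the same edit."""
    iv = call.interval
    left = window.slice(window.offset, iv.start)
    right = window.slice(iv.end, window.end)
    return left + call.alt_allele + right


class SampleVariantSet:
    """A sample's collection of normalized variant calls, unique by key.

    Iteration order follows insertion, but every downstream count is
    key-set-based and therefore order-insensitive.
    """

    def __init__(
        self,
        sample_id: str,
        role: SampleRole | str,
        calls: Iterable[VariantCall] = (),
    ) -> None:
        self.sample_id = sample_id
        self.role = SampleRole(role)
        self._calls: dict[VariantKey, VariantCall] = {}
        for c in calls:
            self.add(c)

    def add(self, call: VariantCall) -> None:
        k = variant_key(call)
        if k in self._calls:
            raise ValueError(f"duplicate variant key {k} in sample {self.sample_id}")
        self._calls[k] = call

    def __len__(self) -> int:
        return len(self._calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self._calls.values())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._calls

    def get(self, key: VariantKey) -> Optional[VariantCall]:
        return self._calls.get(key)

    def keys(self) -> set[VariantKey]:
        return set(self._calls)

    def called_keys(self) -> set[VariantKey]:
        """Keys of calls with status ``called`` (quality-passed)."""
        return {
            k for k, c in self._calls.items() if c.call_status is CallStatus.CALLED
        }

    def filter(self, predicate) -> "SampleVariantSet":
        return SampleVariantSet(
            self.sample_id, self.role, (c for c in self if predicate(c))
        )

    def __repr__(self) -> str:
        return (
            f"SampleVariantSet({self.sample_id!r}, role={self.role.value}, "
            f"n={len(self)})"
        )
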