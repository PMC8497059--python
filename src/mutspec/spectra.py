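"""Strand-collapsed mutation spectra.

A mutation spectrum summarises single-base substitutions into six classes
obtained by collapsing reverse-complement equivalents onto the A/C-centered
representative (G>T is reported as C>A, and so on), optionally extended with
single base-pair insertions and deletions for an eight-class spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The six strand-collapsed substitution classes, in canonical order.
SUB_CLASSES: tuple[str, ...] = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")

#: Single base-pair indel classes appended for eight-class spectra.
INDEL_CLASSES: tuple[str, ...] = ("ins1", "del1")

ALL_CLASSES: tuple[str, ...] = SUB_CLASSES + INDEL_CLASSES

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def complement(base: str) -> str:
    """Complement of a single uppercase base."""
    return _COMPLEMENT[base]


def collapse_substitution(ref: str, alt: str) -> str:
    """Collapse a ref>alt substitution onto its A/C-centered class.

    Purine-reference changes (G or T) are reported as the reverse complement,
    so every substitution falls into one of ``SUB_CLASSES``.

    >>> collapse_substitution("G", "T")
    'C>A'
    >>> collapse_substitution("A", "G")
    'A>G'
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref}")
    if ref in "GT":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass
class SpectrumCounts:
    """Counts over the 6 substitution classes plus optional 1-bp indels.

    Parameters
    ----------
    counts
        Mapping from class label to a non-negative count.  Missing classes
        count as zero.  Allowed keys are ``SUB_CLASSES`` and, when
        ``include_indels`` is true, ``INDEL_CLASSES``.
    include_indels
        Whether the spectrum carries the two single-bp indel categories
        (eight classes total) or substitutions only (six).
    """

    counts: dict[str, float] = field(default_factory=dict)
    include_indels: bool = False

    def __post_init__(self) -> None:
        allowed = set(self.classes)
        for k, v in self.counts.items():
            if k not in allowed:
                raise ValueError(f"unknown spectrum class {k!r}")
            if v < 0:
                raise ValueError(f"negative count for {k}: {v}")
        self.counts = {c: float(self.counts.get(c, 0.0)) for c in self.classes}

    @property
    def classes(self) -> tuple[str, ...]:
        return ALL_CLASSES if self.include_indels else SUB_CLASSES

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def to_vector(self) -> np.ndarray:
        return np.array([self.counts[c] for c in self.classes], dtype=float)

    def normalized(self) -> np.ndarray:
        """Class proportions; sums to 1 when total > 0."""
        v = self.to_vector()
        t = v.sum()
        if t == 0:
            return v
        return v / t

    def add(self, cls: str, weight: float = 1.0) -> None:
        if cls not in self.counts:
            raise ValueError(f"unknown spectrum class {cls!r}")
        self.counts[cls] += weight

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(self.classes), name="count")

    @classmethod
    def from_series(cls, s: pd.Series, include_indels: bool | None = None) -> "SpectrumCounts":
        if include_indels is None:
            include_indels = any(c in s.index for c in INDEL_CLASSES)
        return cls({str(k): float(v) for k, v in s.items()}, include_indels=include_indels)


def read_spectrum_tsv(path) -> SpectrumCounts:
    """Read a two-column (class, count) TSV written by :func:`write_spectrum_tsv`."""
    df = pd.read_csv(path, sep="\t")
    s = pd.Series(df["count"].values, index=df["class"].values)
    return SpectrumCounts.from_series(s)


def write_spectrum_tsv(spectrum: SpectrumCounts, path) -> None:
    df = pd.DataFrame({"class": list(spectrum.classes),
                       "count": [spectrum.counts[c] for c in spectrum.classes]})
    df.to_csv(path, sep="\t", index=False)
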