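"""Methylation array platform descriptors.

A platform fixes the CpG locus universe (column space) of a beta matrix and
the missingness threshold above which a sample is dropped from training.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Platform:
    """An Illumina-style methylation array platform.

    Parameters
    ----------
    name
        Short tag, e.g. ``"27k"``, ``"450k"`` or ``"custom"``.
    n_loci
        Number of CpG probes on the array.
    rejection_threshold
        Samples whose fraction of missing probes strictly exceeds this
        value are rejected during preprocessing.  ``None`` for custom
        platforms, where the caller must supply a threshold explicitly.
    """

    name: str
    n_loci: int
    rejection_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("platform must have at least one locus")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name}({self.n_loci})"


#: Illumina Infinium HumanMethylation27 BeadChip.
P27K = Platform("27k", 27_578, rejection_threshold=0.10)

#: Illumina Infinium HumanMethylation450 BeadChip.
P450K = Platform("450k", 485_764, rejection_threshold=0.20)


def custom(n_loci: int) -> Platform:
    """A desk-scale platform with ``n_loci`` probes and no implied threshold."""
    return Platform("custom", n_loci)


_REGISTRY = {"27k": P27K, "450k": P450K}


def get_platform(name: str, n_loci: int | None = None) -> Platform:
    """Resolve a platform by name; ``custom`` requires ``n_loci``."""
    if name in _REGISTRY:
        return _REGISTRY[name]
    if name == "custom":
        if n_loci is None:
            raise ValueError("custom platform requires n_loci")
        return custom(n_loci)
    raise ValueError(f"unknown platform {name!r}")
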