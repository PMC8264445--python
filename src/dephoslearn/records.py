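"""Core domain types for window-based dephosphorylation-site datasets.

A *site* is an S, T or Y residue on a protein, labelled positive
(experimentally known to be dephosphorylated) or negative (an in-class
residue with no such annotation).  A *window* is the odd-length
subsequence centred on the site; the flank is ``(w - 1) // 2`` residues
on each side and no filler characters are ever inserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Nonstandard letters tolerated in sequences; they map to the unknown
#: token at encoding time instead of causing sites to be dropped.
NONSTANDARD_AA = "XUBZO"
VALID_AA = set(STANDARD_AA) | set(NONSTANDARD_AA)

RESIDUE_CLASSES = {"ST": ("S", "T"), "Y": ("Y",)}

STAGES = ("raw", "deduplicated", "balanced", "split")


class ValidationError(ValueError):
    """Raised when an input record violates a dataset invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence identified by its accession."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        return self.sequence[position - 1]


@dataclass(frozen=True)
class SiteAnnotation:
    """A labelled S/T/Y position on a protein (1-based coordinates)."""

    protein_id: str
    position: int
    residue: str
    label: str
    source: str = "other"

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise ValidationError(
                f"{self.protein_id}:{self.position}: residue must be S/T/Y, "
                f"got {self.residue!r}"
            )
        if self.label not in ("positive", "negative"):
            raise ValidationError(
                f"{self.protein_id}:{self.position}: bad label {self.label!r}"
            )
        if self.position < 1:
            raise ValidationError(
                f"{self.protein_id}: position must be >= 1, got {self.position}"
            )

    def validate_against(self, protein: ProteinRecord) -> None:
        if self.position > len(protein):
            raise ValidationError(
                f"{self.protein_id}:{self.position}: beyond sequence "
                f"length {len(protein)}"
            )
        actual = protein.residue(self.position)
        if actual != self.residue:
            raise ValidationError(
                f"{self.protein_id}:{self.position}: annotated {self.residue} "
                f"but sequence has {actual}"
            )


@dataclass(frozen=True)
class WindowExample:
    """An odd-length window centred on an annotated site."""

    window: str
    center_residue: str
    label: str
    protein_id: str
    position: int

    def __post_init__(self) -> None:
        w = len(self.window)
        if w % 2 == 0:
            raise ValidationError(f"window length {w} is even")
        if "-" in self.window:
            raise ValidationError("window contains filler characters")
        if self.window[w // 2] != self.center_residue:
            raise ValidationError(
                f"window centre {self.window[w // 2]!r} != annotated "
                f"residue {self.center_residue!r}"
            )


@dataclass
class SiteDataset:
    """A collection of same-length windows at a given pipeline stage."""

    examples: list[WindowExample]
    residue_class: str
    window_size: int
    stage: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residue_class not in RESIDUE_CLASSES:
            raise ValidationError(f"bad residue class {self.residue_class!r}")
        if self.window_size % 2 == 0:
            raise ValidationError(f"window size {self.window_size} is even")
        if self.stage not in STAGES:
            raise ValidationError(f"bad stage {self.stage!r}")
        for ex in self.examples:
            if len(ex.window) != self.window_size:
                raise ValidationError(
                    f"{ex.protein_id}:{ex.position}: window length "
                    f"{len(ex.window)} != dataset size {self.window_size}"
                )

    def __len__(self) -> int:
        return len(self.examples)

    def __iter__(self) -> Iterator[WindowExample]:
        return iter(self.examples)

    @property
    def flank(self) -> int:
        return (self.window_size - 1) // 2

    def by_label(self, label: str) -> list[WindowExample]:
        return [ex for ex in self.examples if ex.label == label]

    def count(self, label: str) -> int:
        return sum(1 for ex in self.examples if ex.label == label)

    def with_examples(
        self, examples: Iterable[WindowExample], stage: str | None = None
    ) -> "SiteDataset":
        """Copy of this dataset with new examples (and optionally stage)."""
        return replace(
            self,
            examples=list(examples),
            stage=self.stage if stage is None else stage,
            meta=dict(self.meta),
        )
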