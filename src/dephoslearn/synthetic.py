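"""Synthetic sequence-window tasks with controlled motif signal.

Positives carry a preferred residue at a small set of offsets around
the centre with probability ``q`` (independently per offset); negatives
are pure i.i.d. background, uniform over the 20 standard amino acids.
The centre is always drawn from the residue class (S/T or Y), so class
membership itself carries no signal.  A *related task pair* shares a
tunable fraction of its motif positions with a source task, emulating
the partial overlap between the sequence determinants of two related
modification chemistries — the relatedness that makes transfer
learning from a data-rich task to a data-poor one worthwhile.

Generated tasks can be emitted as FASTA + site-table files (each window
embedded in random protein flanks) so the dataset-preparation pipeline
can be exercised end to end on them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .dataset_prep import write_fasta, write_site_table
from .records import (
    RESIDUE_CLASSES,
    STANDARD_AA,
    ProteinRecord,
    SiteAnnotation,
    SiteDataset,
    WindowExample,
)

LETTERS = np.array(list(STANDARD_AA))


@dataclass(frozen=True)
class MotifSpec:
    """Positions, preferences and strength of the planted motif.

    ``motif_positions`` are offsets relative to the centre (offset 0 is
    excluded — the centre is fixed by the residue class); ``q`` is the
    probability that a positive window carries the preferred residue at
    a motif position.
    """

    motif_positions: tuple[int, ...]
    preferred_residues: tuple[str, ...]
    q: float
    residue_class: str = "ST"
    window_size: int = 31
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.q <= 1:
            raise ValueError(f"q must be in [0, 1]: {self.q}")
        if len(self.motif_positions) != len(self.preferred_residues):
            raise ValueError("one preferred residue per motif position required")
        flank = (self.window_size - 1) // 2
        for off in self.motif_positions:
            if off == 0:
                raise ValueError("offset 0 is the centre; motifs exclude it")
            if abs(off) > flank:
                raise ValueError(f"offset {off} beyond flank {flank}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def default_motif_spec(window_size: int = 31, residue_class: str = "ST",
                       q: float = 0.9, n_positions: int = 4,
                       seed: int = 0) -> MotifSpec:
    """A reproducible random motif: ``n_positions`` distinct non-centre
    offsets, each with a random preferred residue."""
    rng = np.random.default_rng(seed)
    flank = (window_size - 1) // 2
    candidates = [o for o in range(-flank, flank + 1) if o != 0]
    offsets = tuple(
        int(o) for o in sorted(rng.choice(candidates, size=n_positions,
                                          replace=False))
    )
    preferred = tuple(str(a) for a in rng.choice(LETTERS, size=n_positions))
    return MotifSpec(
        motif_positions=offsets,
        preferred_residues=preferred,
        q=q,
        residue_class=residue_class,
        window_size=window_size,
        seed=seed,
    )


def _random_windows(rng: np.random.Generator, n: int, window_size: int,
                    residue_class: str,
                    frequencies: np.ndarray | None = None) -> np.ndarray:
    """(n, w) char array: background letters (uniform by default, or from
    a 20-long frequency vector over the alphabetically ordered standard
    amino acids), class residue at the centre."""
    if frequencies is not None:
        frequencies = np.asarray(frequencies, dtype=float)
        if frequencies.shape != (20,) or not np.isclose(frequencies.sum(), 1.0):
            raise ValueError("frequencies must be 20 probabilities summing to 1")
    mat = rng.choice(LETTERS, size=(n, window_size), p=frequencies)
    centers = np.array(RESIDUE_CLASSES[residue_class])
    mat[:, window_size // 2] = rng.choice(centers, size=n)
    return mat


def _to_dataset(mat: np.ndarray, label: str, residue_class: str,
                prefix: str, stage: str = "raw") -> list[WindowExample]:
    w = mat.shape[1]
    return [
        WindowExample(
            window="".join(row),
            center_residue=row[w // 2],
            label=label,
            protein_id=f"{prefix}{i:06d}",
            position=(w + 1) // 2,
        )
        for i, row in enumerate(mat)
    ]


def sample_background(n: int, window_size: int, residue_class: str,
                      seed: int,
                      frequencies: np.ndarray | None = None) -> SiteDataset:
    """Pure-background negative windows."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mat = _random_windows(rng, n, window_size, residue_class, frequencies)
    return SiteDataset(
        examples=_to_dataset(mat, "negative", residue_class, "BG"),
        residue_class=residue_class,
        window_size=window_size,
    )


def make_motif_task(spec: MotifSpec, n_pos: int, n_neg: int,
                    out_dir: str | Path | None = None,
                    seed: int | None = None,
                    frequencies: np.ndarray | None = None) -> SiteDataset:
    """Balanced (when n_pos == n_neg) positive/negative window task.

    Positives receive the preferred residue at each motif offset with
    probability ``q``; negatives are untouched background.  With
    ``out_dir`` set, the task is additionally written as FASTA +
    site-table files (windows embedded in random flanks) for round-trips
    through the dataset-preparation pipeline.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    center = spec.window_size // 2

    pos = _random_windows(rng, n_pos, spec.window_size, spec.residue_class,
                          frequencies)
    for off, aa in zip(spec.motif_positions, spec.preferred_residues):
        hit = rng.random(n_pos) < spec.q
        pos[hit, center + off] = aa
    neg = _random_windows(rng, n_neg, spec.window_size, spec.residue_class,
                          frequencies)

    examples = _to_dataset(pos, "positive", spec.residue_class, "POS") + \
        _to_dataset(neg, "negative", spec.residue_class, "NEG")
    stage = "balanced" if n_pos == n_neg else "raw"
    dataset = SiteDataset(
        examples=examples,
        residue_class=spec.residue_class,
        window_size=spec.window_size,
        stage=stage,
        meta={"motif_spec": asdict(spec)},
    )
    if out_dir is not None:
        emit_task_files(dataset, spec, Path(out_dir), rng)
    return dataset


def emit_task_files(dataset: SiteDataset, spec: MotifSpec, out_dir: Path,
                    rng: np.random.Generator, max_extra_flank: int = 6) -> None:
    """Write the task as FASTA + site TSV, each window wrapped in a fake
    protein with random extra flanks so re-extraction is exact."""
    out_dir.mkdir(parents=True, exist_ok=True)
    proteins: list[ProteinRecord] = []
    sites: list[SiteAnnotation] = []
    for ex in dataset:
        left = "".join(rng.choice(LETTERS, size=int(rng.integers(0, max_extra_flank + 1))))
        right = "".join(rng.choice(LETTERS, size=int(rng.integers(0, max_extra_flank + 1))))
        sequence = left + ex.window + right
        position = len(left) + dataset.flank + 1
        proteins.append(ProteinRecord(id=ex.protein_id, sequence=sequence))
        sites.append(
            SiteAnnotation(
                protein_id=ex.protein_id,
                position=position,
                residue=ex.center_residue,
                label=ex.label,
                source="synthetic",
            )
        )
    write_fasta(proteins, out_dir / "proteins.fasta")
    write_site_table(sites, out_dir / "sites.tsv")
    spec.to_json(out_dir / "motif_spec.json")


def make_related_task_pair(
    source_spec: MotifSpec,
    overlap: float,
    n_source: int,
    n_target: int,
    seed: int,
) -> tuple[SiteDataset, SiteDataset, MotifSpec]:
    """A large source task and a small target task with shared motif.

    The target keeps ``round(overlap * m)`` of the source's ``m`` motif
    positions (chosen deterministically by seed) and replaces the rest
    with fresh positions and preferences.  Returns (source dataset,
    target dataset, target motif spec).
    """
    if not 0 <= overlap <= 1:
        raise ValueError(f"overlap must be in [0, 1]: {overlap}")
    rng = np.random.default_rng(seed)
    m = len(source_spec.motif_positions)
    n_keep = int(round(overlap * m))
    keep_idx = sorted(rng.choice(m, size=n_keep, replace=False).tolist())

    kept_positions = [source_spec.motif_positions[i] for i in keep_idx]
    kept_residues = [source_spec.preferred_residues[i] for i in keep_idx]

    flank = (source_spec.window_size - 1) // 2
    available = [
        o for o in range(-flank, flank + 1)
        if o != 0 and o not in source_spec.motif_positions
    ]
    n_new = m - n_keep
    new_positions = [
        int(o) for o in rng.choice(available, size=n_new, replace=False)
    ]
    new_residues = [str(a) for a in rng.choice(LETTERS, size=n_new)]

    order = np.argsort(kept_positions + new_positions)
    all_pos = tuple(np.array(kept_positions + new_positions)[order].tolist())
    all_res = tuple(np.array(kept_residues + new_residues)[order].tolist())
    target_spec = MotifSpec(
        motif_positions=all_pos,
        preferred_residues=all_res,
        q=source_spec.q,
        residue_class=source_spec.residue_class,
        window_size=source_spec.window_size,
        seed=int(rng.integers(0, 2**31)),
    )
    source = make_motif_task(source_spec, n_source // 2, n_source - n_source // 2,
                             seed=int(rng.integers(0, 2**31)))
    target = make_motif_task(target_spec, n_target // 2, n_target - n_target // 2,
                             seed=int(rng.integers(0, 2**31)))
    return source, target, target_spec


# Corpus sizes emulated by the full-scale preset: a phosphorylation-style
# source of 31,944 positives + as many negatives, an ST dephosphorylation
# target of 1,112 + 1,112, and a Y target of 125 + 125.
CORPUS_SHAPES = {
    "source_positives": 31_944,
    "st_target_positives": 1_112,
    "y_target_positives": 125,
}


def emulate_corpus_shapes(seed: int, scale: float = 1.0,
                         window_size: int = 31) -> dict[str, SiteDataset]:
    """Source / ST-target / Y-target bundle with realistic size ratios.

    Motif overlap is 0.75 between the source and the ST target (related
    but distinct recognition determinants) and again between the ST and
    Y targets.  ``scale`` shrinks every corpus proportionally for desk
    runs; class balance is preserved exactly.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    n = {k: max(2, int(round(v * scale))) for k, v in CORPUS_SHAPES.items()}

    source_spec = default_motif_spec(window_size=window_size, residue_class="ST",
                                     q=0.85, n_positions=4,
                                     seed=int(rng.integers(0, 2**31)))
    source, st_target, st_spec = make_related_task_pair(
        source_spec, overlap=0.75,
        n_source=2 * n["source_positives"],
        n_target=2 * n["st_target_positives"],
        seed=int(rng.integers(0, 2**31)),
    )
    y_spec_base = MotifSpec(
        motif_positions=st_spec.motif_positions,
        preferred_residues=st_spec.preferred_residues,
        q=st_spec.q,
        residue_class="Y",
        window_size=window_size,
        seed=int(rng.integers(0, 2**31)),
    )
    _, y_target, _ = make_related_task_pair(
        y_spec_base, overlap=0.75,
        n_source=2,  # discarded; only the target matters here
        n_target=2 * n["y_target_positives"],
        seed=int(rng.integers(0, 2**31)),
    )
    return {"source": source, "st_target": st_target, "y_target": y_target}
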