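"""Construction of balanced, non-redundant window datasets.

The pipeline mirrors the standard PTM-predictor recipe: extract an
odd-length window around every annotated site (dropping sites whose full
flank does not fit inside the protein — no filler padding), generate
negatives from every other in-class residue on the same proteins, remove
exact duplicate windows within and across labels, under-sample the
majority class to balance, and split 80/20 stratified by label.

Coordinates are 1-based and fully closed throughout, matching
UniProt-style site tables; the window centre is index ``(w + 1) / 2``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .records import (
    RESIDUE_CLASSES,
    ProteinRecord,
    SiteAnnotation,
    SiteDataset,
    ValidationError,
    WindowExample,
)

SITE_TABLE_COLUMNS = ["protein_id", "position", "residue", "label", "source"]
WINDOW_TABLE_COLUMNS = ["window", "center_residue", "label", "protein_id", "position"]


# ---------------------------------------------------------------------------
# I/O


def load_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords (sequences uppercased).

    Duplicate accessions are rejected: a site table cannot be validated
    against an ambiguous id.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValidationError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq).upper()))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def load_site_table(
    path: str | Path,
    proteins: list[ProteinRecord],
    strict: bool = True,
) -> list[SiteAnnotation]:
    """Read a TSV of site annotations and validate against the proteins.

    Every row must name a known protein whose residue at the stated
    1-based position matches the annotated residue.  In strict mode any
    invalid row aborts with a message listing all offenders; in
    permissive mode invalid rows are dropped (their count is recorded on
    the returned list via ``load_site_table.last_dropped``).
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str})
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    by_id = {p.id: p for p in proteins}

    accepted: list[SiteAnnotation] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            ann = SiteAnnotation(
                protein_id=row["protein_id"],
                position=int(row["position"]),
                residue=row["residue"],
                label=row["label"],
                source=str(row["source"]),
            )
            protein = by_id.get(ann.protein_id)
            if protein is None:
                raise ValidationError(
                    f"{ann.protein_id}: unknown protein id (row {idx})"
                )
            ann.validate_against(protein)
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {idx}: {exc}")
            continue
        accepted.append(ann)

    if errors and strict:
        raise ValidationError(
            f"{path}: {len(errors)} invalid site rows:\n" + "\n".join(errors)
        )
    load_site_table.last_dropped = len(errors)  # type: ignore[attr-defined]
    return accepted


load_site_table.last_dropped = 0  # type: ignore[attr-defined]


def write_site_table(sites: list[SiteAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            (s.protein_id, s.position, s.residue, s.label, s.source)
            for s in sites
        ],
        columns=SITE_TABLE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_window_table(dataset: SiteDataset, path: str | Path) -> None:
    dataset_to_frame(dataset).to_csv(path, sep="\t", index=False)


def load_window_table(
    path: str | Path, residue_class: str, stage: str = "raw"
) -> SiteDataset:
    df = pd.read_csv(path, sep="\t", dtype={"window": str, "protein_id": str})
    examples = [
        WindowExample(
            window=row.window,
            center_residue=row.center_residue,
            label=row.label,
            protein_id=row.protein_id,
            position=int(row.position),
        )
        for row in df.itertuples()
    ]
    if not examples:
        raise ValidationError(f"{path}: empty window table")
    return SiteDataset(
        examples=examples,
        residue_class=residue_class,
        window_size=len(examples[0].window),
        stage=stage,
    )


def dataset_to_frame(dataset: SiteDataset) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.window, e.center_residue, e.label, e.protein_id, e.position)
            for e in dataset
        ],
        columns=WINDOW_TABLE_COLUMNS,
    )


# ---------------------------------------------------------------------------
# Window extraction and negative generation


@dataclass
class DropReport:
    """Bookkeeping for sites silently dropped or removed by a stage."""

    dropped_left: int = 0
    dropped_right: int = 0
    within_label_duplicates: int = 0
    cross_label_conflicts: int = 0
    majority_removed: int = 0

    @property
    def total_dropped(self) -> int:
        return self.dropped_left + self.dropped_right

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")


def extract_windows(
    proteins: list[ProteinRecord],
    sites: list[SiteAnnotation],
    window_size: int,
    residue_class: str | None = None,
) -> tuple[SiteDataset, DropReport]:
    """Cut one window per site; sites too close to a terminus are dropped.

    A site at 1-based position ``p`` on a protein of length ``L`` yields
    a window iff ``p - flank >= 1`` and ``p + flank <= L`` where
    ``flank = (window_size - 1) // 2``.  Dropped sites are counted in the
    returned report rather than padded with fillers.
    """
    if window_size % 2 == 0:
        raise ValidationError(f"window size must be odd, got {window_size}")
    flank = (window_size - 1) // 2
    by_id = {p.id: p for p in proteins}
    if residue_class is None:
        residues = {s.residue for s in sites}
        residue_class = "Y" if residues <= {"Y"} else "ST"

    report = DropReport()
    examples: list[WindowExample] = []
    for site in sites:
        protein = by_id[site.protein_id]
        if site.position - flank < 1:
            report.dropped_left += 1
            continue
        if site.position + flank > len(protein):
            report.dropped_right += 1
            continue
        window = protein.sequence[site.position - flank - 1 : site.position + flank]
        examples.append(
            WindowExample(
                window=window,
                center_residue=site.residue,
                label=site.label,
                protein_id=site.protein_id,
                position=site.position,
            )
        )
    dataset = SiteDataset(
        examples=examples,
        residue_class=residue_class,
        window_size=window_size,
        stage="raw",
    )
    return dataset, report


def generate_negative_sites(
    proteins: list[ProteinRecord],
    positives: list[SiteAnnotation],
    residue_class: str,
    source: str = "other",
) -> list[SiteAnnotation]:
    """Annotate every in-class residue that is not a known positive as negative.

    Only proteins appearing in the positive annotation table contribute
    negatives (the site tables describe substrate proteins, not a whole
    proteome).
    """
    class_residues = set(RESIDUE_CLASSES[residue_class])
    positive_keys = {(s.protein_id, s.position) for s in positives}
    annotated_ids = sorted({s.protein_id for s in positives})
    by_id = {p.id: p for p in proteins}

    negatives: list[SiteAnnotation] = []
    for pid in annotated_ids:
        protein = by_id[pid]
        for pos0, letter in enumerate(protein.sequence):
            pos = pos0 + 1
            if letter in class_residues and (pid, pos) not in positive_keys:
                negatives.append(
                    SiteAnnotation(
                        protein_id=pid,
                        position=pos,
                        residue=letter,
                        label="negative",
                        source=source,
                    )
                )
    return negatives


# ---------------------------------------------------------------------------
# Redundancy removal, balancing, splitting


def deduplicate(dataset: SiteDataset) -> tuple[SiteDataset, DropReport]:
    """Collapse duplicate windows within a label; delete cross-label conflicts.

    Within one label the first occurrence (ordered by protein id, then
    position) survives.  A window string seen under both labels is
    removed from BOTH labels, since its true label is ambiguous.
    """
    report = DropReport()
    ordered = sorted(dataset.examples, key=lambda e: (e.protein_id, e.position))

    first_by_key: dict[tuple[str, str], WindowExample] = {}
    for ex in ordered:
        key = (ex.window, ex.label)
        if key in first_by_key:
            report.within_label_duplicates += 1
        else:
            first_by_key[key] = ex

    pos_windows = {w for (w, lab) in first_by_key if lab == "positive"}
    neg_windows = {w for (w, lab) in first_by_key if lab == "negative"}
    conflicted = pos_windows & neg_windows
    report.cross_label_conflicts = 2 * len(conflicted)

    survivors = [
        ex
        for ex in ordered
        if (ex.window, ex.label) in first_by_key
        and first_by_key[(ex.window, ex.label)] is ex
        and ex.window not in conflicted
    ]
    return dataset.with_examples(survivors, stage="deduplicated"), report


def balance_undersample(dataset: SiteDataset, seed: int) -> SiteDataset:
    """Randomly down-sample the majority label to the minority count.

    Sampling is without replacement and deterministic for a fixed seed.
    The rule is symmetric: whichever label is in the majority is reduced.
    """
    pos = dataset.by_label("positive")
    neg = dataset.by_label("negative")
    if not pos or not neg:
        raise ValidationError("cannot balance: one label class is empty")
    if len(pos) == len(neg):
        return dataset.with_examples(dataset.examples, stage="balanced")

    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    rng = np.random.default_rng(seed)
    keep_idx = rng.choice(len(majority), size=len(minority), replace=False)
    kept = [majority[i] for i in sorted(keep_idx)]
    survivors = sorted(
        minority + kept, key=lambda e: (e.protein_id, e.position, e.label)
    )
    out = dataset.with_examples(survivors, stage="balanced")
    out.meta["majority_removed"] = len(majority) - len(minority)
    return out


def split_train_test(
    dataset: SiteDataset, train_fraction: float, seed: int
) -> tuple[SiteDataset, SiteDataset]:
    """Stratified train/test split with per-label rounding.

    Per label, ``round(train_fraction * n_label)`` examples go to the
    training partition; the remainder to the test partition.
    """
    if not 0 < train_fraction < 1:
        raise ValidationError(f"train fraction must be in (0, 1): {train_fraction}")
    rng = np.random.default_rng(seed)
    train: list[WindowExample] = []
    test: list[WindowExample] = []
    for label in ("positive", "negative"):
        group = dataset.by_label(label)
        if len(group) < 2:
            raise ValidationError(f"label {label!r} has < 2 examples; cannot split")
        n_train = int(round(train_fraction * len(group)))
        n_train = min(max(n_train, 1), len(group) - 1)
        order = rng.permutation(len(group))
        train.extend(group[i] for i in sorted(order[:n_train]))
        test.extend(group[i] for i in sorted(order[n_train:]))
    key = lambda e: (e.protein_id, e.position, e.label)
    return (
        dataset.with_examples(sorted(train, key=key), stage="split"),
        dataset.with_examples(sorted(test, key=key), stage="split"),
    )


def shrink_window(
    dataset: SiteDataset, target_size: int
) -> tuple[SiteDataset, DropReport]:
    """Trim windows symmetrically to a smaller odd size, then re-deduplicate.

    Removing residues from both ends preserves the centre; trimming can
    create new exact duplicates, so deduplication is re-applied.
    """
    if target_size % 2 == 0:
        raise ValidationError(f"target size must be odd, got {target_size}")
    if target_size > dataset.window_size:
        raise ValidationError(
            f"target {target_size} exceeds current window {dataset.window_size}"
        )
    if target_size == dataset.window_size:
        return dataset, DropReport()
    trim = (dataset.window_size - target_size) // 2
    trimmed = [
        WindowExample(
            window=ex.window[trim:-trim],
            center_residue=ex.center_residue,
            label=ex.label,
            protein_id=ex.protein_id,
            position=ex.position,
        )
        for ex in dataset
    ]
    shrunk = SiteDataset(
        examples=trimmed,
        residue_class=dataset.residue_class,
        window_size=target_size,
        stage="raw",
        meta=dict(dataset.meta),
    )
    out, report = deduplicate(shrunk)
    if dataset.stage == "balanced" and out.count("positive") == out.count("negative"):
        out.stage = "balanced"
    return out, report


def merge_datasets(
    a: SiteDataset, b: SiteDataset
) -> tuple[SiteDataset, DropReport]:
    """Union of two window datasets followed by duplicate removal."""
    if a.residue_class != b.residue_class:
        raise ValidationError(
            f"residue class mismatch: {a.residue_class} vs {b.residue_class}"
        )
    if a.window_size != b.window_size:
        raise ValidationError(
            f"window size mismatch: {a.window_size} vs {b.window_size}"
        )
    merged = SiteDataset(
        examples=list(a.examples) + list(b.examples),
        residue_class=a.residue_class,
        window_size=a.window_size,
        stage="raw",
    )
    return deduplicate(merged)


# ---------------------------------------------------------------------------
# Summaries


@dataclass
class DatasetStats:
    """Counts by label/residue plus the fold-ratio helper."""

    total: int
    positives: int
    negatives: int
    by_residue: dict = field(default_factory=dict)
    stage: str = "raw"
    window_size: int = 0

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "positives": self.positives,
            "negatives": self.negatives,
            "by_residue": dict(self.by_residue),
            "stage": self.stage,
            "window_size": self.window_size,
        }


def dataset_stats(dataset: SiteDataset) -> DatasetStats:
    by_residue: dict[str, int] = {}
    for ex in dataset:
        by_residue[ex.center_residue] = by_residue.get(ex.center_residue, 0) + 1
    return DatasetStats(
        total=len(dataset),
        positives=dataset.count("positive"),
        negatives=dataset.count("negative"),
        by_residue=by_residue,
        stage=dataset.stage,
        window_size=dataset.window_size,
    )


def fold_ratio(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Size ratio between two corpora (e.g. an expansion factor), rounded
    half-away-from-zero to ``decimals`` places."""
    if denominator == 0:
        raise ValidationError("fold ratio denominator is zero")
    value = numerator / denominator
    scale = 10**decimals
    return math.copysign(math.floor(abs(value) * scale + 0.5) / scale, value)


def prepare_dataset(
    proteins: list[ProteinRecord],
    positives: list[SiteAnnotation],
    residue_class: str,
    window_size: int,
    seed: int,
    train_fraction: float = 0.8,
) -> dict:
    """Full pipeline: negatives -> windows -> dedup -> balance -> split.

    Returns a dict with the train/test datasets and all stage reports.
    """
    negatives = generate_negative_sites(proteins, positives, residue_class)
    raw, drop_report = extract_windows(
        proteins, positives + negatives, window_size, residue_class
    )
    dedup, dedup_report = deduplicate(raw)
    balanced = balance_undersample(dedup, seed=seed)
    train, test = split_train_test(balanced, train_fraction, seed=seed)
    return {
        "train": train,
        "test": test,
        "balanced": balanced,
        "drop_report": drop_report,
        "dedup_report": dedup_report,
        "stats": dataset_stats(balanced),
    }
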