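"""Shared fixtures: tiny proteins, site tables, and desk-scale model specs.

All fixture data is generated programmatically; training fixtures use
deliberately small networks and corpora so the whole suite runs on one
CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from dephoslearn.dataset_prep import write_fasta, write_site_table
from dephoslearn.model import ModelSpec
from dephoslearn.records import STANDARD_AA, ProteinRecord, SiteAnnotation


def random_protein(rng: np.random.Generator, pid: str,
                   length: int) -> ProteinRecord:
    seq = "".join(rng.choice(list(STANDARD_AA), size=length))
    return ProteinRecord(id=pid, sequence=seq)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_proteins():
    """Three hand-built proteins with known S/T/Y placement."""
    return [
        # S at 3, 17; T at 10; Y at 20 (1-based)
        ProteinRecord("P1", "AASAAAAAATAAAAAASAAYAAAAAAAAAAAAA"),  # length 33
        ProteinRecord("P2", "MSTYSTYAAAAAAAAAAAAAAAAAAAAAAAAAAAAAASAA"),  # length 40
        ProteinRecord("P3", "AAAAAAAAAAAAAAAAYAAAAAAAAAAAAAAAA"),  # Y at 17, len 33
    ]


@pytest.fixture
def tiny_sites(tiny_proteins):
    return [
        SiteAnnotation("P1", 17, "S", "positive", "synthetic"),
        SiteAnnotation("P2", 5, "S", "positive", "synthetic"),
        SiteAnnotation("P3", 17, "Y", "positive", "synthetic"),
    ]


@pytest.fixture
def fasta_file(tmp_path, tiny_proteins):
    path = tmp_path / "proteins.fasta"
    write_fasta(tiny_proteins, path)
    return path


@pytest.fixture
def sites_file(tmp_path, tiny_sites):
    path = tmp_path / "sites.tsv"
    write_site_table(tiny_sites, path)
    return path


def tiny_spec(**overrides) -> ModelSpec:
    """A small but real instance of the architecture for fast training."""
    defaults = dict(
        window_size=11, embedding_dim=8, bilstm_layers=1, bilstm_units=8,
        time_distributed_units=8, dense_units=8, dropout_rate=0.2,
        batch_size=64, epochs=8, learning_rate=0.01, seed=0,
    )
    defaults.update(overrides)
    return ModelSpec(**defaults)
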