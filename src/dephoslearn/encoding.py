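"""Integer encoding of amino-acid windows.

The 20 standard amino acids map alphabetically to 1..20; any
nonstandard letter (X, U, B, Z, O) maps to the unknown index 21.  Index
0 is reserved: windows are never padded (sites without a full flank are
dropped upstream), but keeping 0 free means a future padded mode would
not renumber the alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import STANDARD_AA, SiteDataset


@dataclass(frozen=True)
class EncodingScheme:
    token_map: dict[str, int] = field(
        default_factory=lambda: {aa: i + 1 for i, aa in enumerate(sorted(STANDARD_AA))}
    )
    unknown_index: int = 21
    vocabulary_size: int = 22

    def encode_char(self, aa: str) -> int:
        return self.token_map.get(aa, self.unknown_index)

    def decode_index(self, idx: int) -> str:
        for aa, i in self.token_map.items():
            if i == idx:
                return aa
        return "X"


def build_encoding() -> EncodingScheme:
    """The canonical (deterministic, alphabetical) encoding scheme."""
    return EncodingScheme()


def encode_windows(
    dataset: SiteDataset | list[str],
    scheme: EncodingScheme | None = None,
    labels: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode windows to an (n, w) integer matrix and one-hot labels.

    Label columns are ordered (negative, positive), so ``Y[:, 1]`` is
    the positive-class indicator.  Row order follows the input order.
    """
    scheme = scheme or build_encoding()
    if isinstance(dataset, SiteDataset):
        windows = [ex.window for ex in dataset]
        labels = [ex.label for ex in dataset]
    else:
        windows = list(dataset)
        labels = list(labels) if labels is not None else ["negative"] * len(windows)

    if not windows:
        raise ValueError("no windows to encode")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("ragged windows: all windows must share one length")

    X = np.array(
        [[scheme.encode_char(aa) for aa in window] for window in windows],
        dtype=np.int64,
    )
    Y = np.zeros((len(windows), 2), dtype=np.float64)
    for i, label in enumerate(labels):
        Y[i, 1 if label == "positive" else 0] = 1.0
    return X, Y


def decode_windows(X: np.ndarray, scheme: EncodingScheme | None = None) -> list[str]:
    scheme = scheme or build_encoding()
    inverse = {i: aa for aa, i in scheme.token_map.items()}
    return ["".join(inverse.get(int(i), "X") for i in row) for row in X]
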