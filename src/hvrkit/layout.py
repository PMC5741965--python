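"""Genome coordinate space: ordered chromosome names and lengths.

All internal coordinates are 0-based half-open; VCF positions (1-based) are
converted at the I/O boundary.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from pathlib import Path
from typing import Iterator


class GenomeLayout:
    """Ordered mapping of chromosome name -> length in bp."""

    def __init__(self, sizes: dict[str, int] | list[tuple[str, int]]):
        items = sizes.items() if isinstance(sizes, dict) else sizes
        self._sizes: OrderedDict[str, int] = OrderedDict()
        for name, length in items:
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome {name!r}")
            self._sizes[name] = length

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column ``chrom.sizes`` file (name, length)."""
        sizes: list[tuple[str, int]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"malformed chrom.sizes line: {line!r}")
                sizes.append((fields[0], int(fields[1])))
        if not sizes:
            raise ValueError(f"empty chrom.sizes file: {path}")
        return cls(sizes)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")

    @property
    def chromosomes(self) -> list[str]:
        return list(self._sizes)

    @property
    def total_bp(self) -> int:
        return sum(self._sizes.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeLayout):
            return NotImplemented
        return list(self._sizes.items()) == list(other._sizes.items())

    def n_windows(self, chrom: str, window_bp: int) -> int:
        """Number of windows tiling ``chrom``; the last window may be short."""
        return math.ceil(self._sizes[chrom] / window_bp)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GenomeLayout({dict(self._sizes)!r})"
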