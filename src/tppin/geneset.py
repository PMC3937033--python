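"""Named gene sets (anchor sets, annotation sets)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers.

    Identifiers are opaque strings; no identifier mapping is attempted.
    """

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "GeneSet":
        """Read a gene set from a one-identifier-per-line text file."""
        path = Path(path)
        members = set()
        with open(path) as fh:
            for line in fh:
                token = line.strip()
                if token and not token.startswith("#"):
                    members.add(token)
        return cls(name or path.stem, frozenset(members))

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gene in sorted(self.members):
                fh.write(gene + "\n")
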