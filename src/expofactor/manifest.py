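"""Variable manifest: declared measurement level of every column.

The manifest drives correlation-type dispatch (Pearson / polyserial /
polychoric) and tells the synthetic generator and the scoring step how
each item is coded.  Levels are ``continuous``, ``ordinal`` (k >= 2
consecutive integer categories 0..k-1) and ``binary`` (ordinal with
exactly 2 categories).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

LEVELS = ("continuous", "ordinal", "binary")


@dataclass(frozen=True)
class VariableInfo:
    name: str
    level: str
    n_categories: int | None = None
    block: str = ""

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r} for {self.name!r}")
        if self.level == "binary" and self.n_categories not in (None, 2):
            raise ValueError(f"binary variable {self.name!r} must have 2 categories")
        if self.level == "ordinal":
            if self.n_categories is None or self.n_categories < 2:
                raise ValueError(
                    f"ordinal variable {self.name!r} needs n_categories >= 2"
                )
        if self.level == "binary" and self.n_categories is None:
            object.__setattr__(self, "n_categories", 2)

    @property
    def is_ordered(self) -> bool:
        return self.level in ("ordinal", "binary")


@dataclass
class VariableManifest:
    variables: list[VariableInfo] = field(default_factory=list)

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in manifest")
        self._by_name = {v.name: v for v in self.variables}

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    def __getitem__(self, name: str) -> VariableInfo:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def subset(self, names) -> "VariableManifest":
        return VariableManifest([self._by_name[n] for n in names])

    def validate_table(self, table: pd.DataFrame) -> None:
        missing = [c for c in table.columns if c not in self._by_name]
        if missing:
            raise ValueError(f"columns not covered by manifest: {missing}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [v.name for v in self.variables],
                "level": [v.level for v in self.variables],
                "n_categories": [v.n_categories for v in self.variables],
                "block": [v.block for v in self.variables],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VariableManifest":
        vars_ = []
        for row in frame.itertuples(index=False):
            ncat = getattr(row, "n_categories", None)
            ncat = None if ncat is None or pd.isna(ncat) else int(ncat)
            block = getattr(row, "block", "") or ""
            if pd.isna(block):
                block = ""
            vars_.append(VariableInfo(str(row.name), str(row.level), ncat, str(block)))
        return cls(vars_)

    @classmethod
    def from_csv(cls, path) -> "VariableManifest":
        return cls.from_frame(pd.read_csv(path))
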