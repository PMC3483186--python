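"""Discrete character matrices (taxon × character) with a missing code.

Backed by a pandas DataFrame; cell values are state symbols (strings) or
the missing code ``"?"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["CharacterMatrix", "CharacterError", "read_character_table"]

MISSING = "?"


class CharacterError(ValueError):
    pass


class CharacterMatrix:
    """Taxon × discrete character table.

    Parameters
    ----------
    data:
        DataFrame indexed by taxon, one column per character; cells hold
        state symbols or the missing code.
    alphabets:
        Optional mapping character -> ordered state tuple.  Missing entries
        are inferred from the observed states (sorted).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        alphabets: Mapping[str, Sequence[str]] | None = None,
        missing_code: str = MISSING,
    ):
        if data.index.duplicated().any():
            dupes = sorted(data.index[data.index.duplicated()])
            raise CharacterError(f"duplicate taxa: {dupes}")
        self.data = data.astype(str)
        self.missing_code = missing_code
        self.alphabets: dict[str, tuple[str, ...]] = {}
        for char in self.data.columns:
            observed = sorted(
                v for v in self.data[char].unique() if v != missing_code
            )
            if alphabets is not None and char in alphabets:
                alpha = tuple(alphabets[char])
                bad = sorted(set(observed) - set(alpha))
                if bad:
                    raise CharacterError(
                        f"character {char!r}: states outside declared "
                        f"alphabet: {bad}"
                    )
            else:
                alpha = tuple(observed)
            if len(alpha) < 2:
                raise CharacterError(
                    f"character {char!r}: alphabet needs >= 2 states"
                )
            self.alphabets[char] = alpha

    # -------------------------------------------------------------- access
    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def characters(self) -> list[str]:
        return list(self.data.columns)

    def states(self, char: str) -> dict[str, str]:
        """taxon -> state symbol (or missing code) for one character."""
        return self.data[char].to_dict()

    def k(self, char: str) -> int:
        return len(self.alphabets[char])

    def subset(self, taxa: Iterable[str]) -> "CharacterMatrix":
        taxa = [t for t in taxa if t in self.data.index]
        return CharacterMatrix(
            self.data.loc[taxa], self.alphabets, self.missing_code
        )

    def rename_taxa(self, fn: Callable[[str], str]) -> "CharacterMatrix":
        renamed = self.data.copy()
        renamed.index = [fn(t) for t in renamed.index]
        renamed = renamed[~renamed.index.duplicated(keep="first")]
        return CharacterMatrix(renamed, self.alphabets, self.missing_code)

    def drop_missing(self, char: str) -> "CharacterMatrix":
        keep = self.data.index[self.data[char] != self.missing_code]
        return self.subset(keep)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<CharacterMatrix {len(self.taxa)} taxa x "
            f"{len(self.characters)} characters>"
        )


def read_character_table(
    path,
    alphabets: Mapping[str, Sequence[str]] | None = None,
    missing_values: Sequence[str] = ("?", "", "NA", "Unknown", "unknown"),
) -> CharacterMatrix:
    """Read a TSV character table (first column taxon, rest characters).

    Entries matching ``missing_values`` become the missing code.  States
    are validated against ``alphabets`` when given; offenders are listed in
    the error.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, comment="#"
        )
    except pd.errors.EmptyDataError:
        raise CharacterError(f"{path}: empty character table") from None
    if df.empty or df.shape[1] < 2:
        raise CharacterError(
            f"{path}: expected a TSV with a taxon column plus >= 1 "
            "character column"
        )
    df = df.set_index(df.columns[0])
    df = df.map(lambda v: MISSING if v.strip() in missing_values else v.strip())
    return CharacterMatrix(df, alphabets)
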