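"""Long-format container for formant measurements.

A *token* is one annotated vowel-like region (one vocalization, or one
annotated stretch of a recording); each token carries measurements of one
or more formants F1..Fn in Hz.  Missing formants are first-class: a missing
F_n keeps its row (with NaN frequency) so that later formants stay
correctly numbered.  Present frequencies must increase strictly with
formant index within a token — resonances of a single tube cannot cross.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormantTable",
    "FormantValidationError",
    "FormantFormatError",
    "COLUMNS",
]

#: canonical long-format column order
COLUMNS = ["token", "speaker", "group", "vowel", "formant_index", "frequency_hz"]

_WIDE_FORMANT_RE = re.compile(r"^f(\d+)$", re.IGNORECASE)
_NA_STRINGS = {"", "na", "nan", "n/a", "none", "null", "--undefined--"}


class FormantValidationError(ValueError):
    """Raised when formant records violate the table invariants."""


class FormantFormatError(ValueError):
    """Raised when an input file cannot be parsed as a formant table."""


def _coerce_frequency(value) -> float:
    """Map blank / NA-like / non-numeric cells to NaN, else float Hz."""
    if value is None:
        return np.nan
    if isinstance(value, str):
        if value.strip().lower() in _NA_STRINGS:
            return np.nan
        try:
            return float(value)
        except ValueError:
            return np.nan
    try:
        out = float(value)
    except (TypeError, ValueError):
        return np.nan
    return out


class FormantTable:
    """Validated long-format table of formant measurements.

    Parameters
    ----------
    data
        DataFrame with columns ``token, speaker, group, vowel,
        formant_index, frequency_hz``.  ``speaker``, ``group`` and
        ``vowel`` may be entirely or partly null.  ``frequency_hz`` may be
        NaN (missing measurement).
    validate
        Check the invariants (positive frequencies, strictly ascending
        present formants within each token, unique (token, index) pairs).
    """

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        df = data.copy()
        for col in COLUMNS:
            if col not in df.columns:
                if col in ("token", "formant_index", "frequency_hz"):
                    raise FormantFormatError(f"required column missing: {col!r}")
                df[col] = None
        df = df[COLUMNS].reset_index(drop=True)
        df["token"] = df["token"].astype(str)
        df["formant_index"] = pd.to_numeric(df["formant_index"], errors="raise").astype(int)
        df["frequency_hz"] = pd.to_numeric(df["frequency_hz"], errors="coerce").astype(float)
        df = df.sort_values(["token", "formant_index"], kind="stable").reset_index(drop=True)
        if validate:
            self._validate(df)
        self.data = df

    # ------------------------------------------------------------------ #
    # validation

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if (df["formant_index"] < 1).any():
            bad = df.loc[df["formant_index"] < 1, "token"].unique().tolist()
            raise FormantValidationError(f"formant_index < 1 in tokens: {bad}")
        present = df["frequency_hz"].notna()
        if (df.loc[present, "frequency_hz"] <= 0).any():
            bad = df.loc[present & (df["frequency_hz"] <= 0), "token"].unique().tolist()
            raise FormantValidationError(f"non-positive frequencies in tokens: {bad}")
        dup = df.duplicated(subset=["token", "formant_index"])
        if dup.any():
            bad = df.loc[dup, "token"].unique().tolist()
            raise FormantValidationError(
                f"duplicate (token, formant_index) pairs in tokens: {bad}"
            )
        offenders = []
        for token, grp in df.loc[present].groupby("token", sort=False):
            f = grp.sort_values("formant_index")["frequency_hz"].to_numpy()
            if len(f) > 1 and not np.all(np.diff(f) > 0):
                offenders.append(token)
        if offenders:
            raise FormantValidationError(
                "present formant frequencies must increase strictly with "
                f"formant index; offending tokens: {offenders}"
            )

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_formants(
        cls,
        formants: Sequence[float | None],
        token: str = "t1",
        speaker: str | None = None,
        group: str | None = None,
        vowel: str | None = None,
        offset: int = 0,
    ) -> "FormantTable":
        """Build a one-token table from a list of frequencies in Hz.

        ``formants[i]`` is F_{i+1+offset}; interior missing values must be
        given explicitly (None/NaN) so indices stay correct.  ``offset``
        shifts all indices up, for tokens whose leading formants were not
        measured at all.
        """
        recs = [
            {
                "token": token,
                "speaker": speaker,
                "group": group,
                "vowel": vowel,
                "formant_index": i + 1 + offset,
                "frequency_hz": _coerce_frequency(f),
            }
            for i, f in enumerate(formants)
        ]
        return cls(pd.DataFrame(recs))

    @classmethod
    def from_wide(cls, df: pd.DataFrame) -> "FormantTable":
        """Convert a wide table (columns f1..fn, case-insensitive) to long.

        A token id is taken from a ``token``/``token_id``/``file`` column
        when present, otherwise from the row number.  The annotation-export
        layout (``start, end, label, f1..fn``) is accepted: each row is one
        token and ``label`` maps to the vowel when no vowel column exists.
        """
        cols = {c.lower().strip(): c for c in df.columns}
        fcols: dict[int, str] = {}
        for low, orig in cols.items():
            m = _WIDE_FORMANT_RE.match(low)
            if m:
                fcols[int(m.group(1))] = orig
        if not fcols:
            raise FormantFormatError(
                "no formant columns found (expected f1..fn, case-insensitive); "
                f"got columns {list(df.columns)}"
            )

        def pick(*names):
            for n in names:
                if n in cols:
                    return cols[n]
            return None

        token_col = pick("token", "token_id", "file", "filename")
        speaker_col = pick("speaker", "speaker_id")
        group_col = pick("group")
        vowel_col = pick("vowel", "label")

        recs = []
        for rownum, (_, row) in enumerate(df.iterrows()):
            token = str(row[token_col]) if token_col else f"row{rownum}"
            if token_col and df[token_col].duplicated().any():
                token = f"{token}_{rownum}"
            for idx in sorted(fcols):
                recs.append(
                    {
                        "token": token,
                        "speaker": row[speaker_col] if speaker_col else None,
                        "group": row[group_col] if group_col else None,
                        "vowel": row[vowel_col] if vowel_col else None,
                        "formant_index": idx,
                        "frequency_hz": _coerce_frequency(row[fcols[idx]]),
                    }
                )
        return cls(pd.DataFrame(recs, columns=COLUMNS))

    @classmethod
    def read_csv(cls, path, layout: str = "wide") -> "FormantTable":
        """Read a formant table from CSV (UTF-8, '.' decimal separator)."""
        try:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
        except pd.errors.ParserError as exc:
            raise FormantFormatError(f"malformed CSV {path}: {exc}") from exc
        if layout == "wide":
            return cls.from_wide(df)
        if layout == "long":
            cols = {c.lower().strip(): c for c in df.columns}
            ren = {}
            for canon, aliases in {
                "token": ("token", "token_id", "file"),
                "speaker": ("speaker", "speaker_id"),
                "group": ("group",),
                "vowel": ("vowel", "label"),
                "formant_index": ("formant_index", "formant", "index"),
                "frequency_hz": ("frequency_hz", "frequency", "hz"),
            }.items():
                for a in aliases:
                    if a in cols:
                        ren[cols[a]] = canon
                        break
            df = df.rename(columns=ren)
            missing = {"token", "formant_index", "frequency_hz"} - set(df.columns)
            if missing:
                raise FormantFormatError(
                    f"long layout requires columns {sorted(missing)} (missing in {path})"
                )
            df["frequency_hz"] = df["frequency_hz"].map(_coerce_frequency)
            for opt in ("speaker", "group", "vowel"):
                if opt in df.columns:
                    df[opt] = df[opt].replace("", None)
            return cls(df)
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")

    # ------------------------------------------------------------------ #
    # export

    def to_csv(self, path, layout: str = "long") -> None:
        """Write to CSV; missing values become empty cells."""
        if layout == "long":
            self.data.to_csv(path, index=False, na_rep="")
        elif layout == "wide":
            self.to_wide().reset_index().to_csv(path, index=False, na_rep="")
        else:
            raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")

    def to_wide(self) -> pd.DataFrame:
        """Pivot to one row per token with columns f1..fn (NaN = missing).

        Speaker/group/vowel metadata (constant within token) is carried
        along.
        """
        piv = self.data.pivot(index="token", columns="formant_index", values="frequency_hz")
        piv.columns = [f"f{int(c)}" for c in piv.columns]
        meta = (
            self.data.groupby("token", sort=False)[["speaker", "group", "vowel"]]
            .first()
        )
        wide = meta.join(piv)
        # keep original token order
        order = self.data["token"].drop_duplicates().tolist()
        return wide.loc[order]

    # ------------------------------------------------------------------ #
    # accessors

    @property
    def tokens(self) -> list[str]:
        return self.data["token"].drop_duplicates().tolist()

    @property
    def speakers(self) -> list:
        sp = self.data["speaker"].dropna().drop_duplicates().tolist()
        return sp

    @property
    def vowels(self) -> list:
        return self.data["vowel"].dropna().drop_duplicates().tolist()

    @property
    def groups(self) -> list:
        return self.data["group"].dropna().drop_duplicates().tolist()

    @property
    def n_tokens(self) -> int:
        return self.data["token"].nunique()

    @property
    def max_formant_index(self) -> int:
        return int(self.data["formant_index"].max())

    def token_formants(self, token: str) -> dict[int, float]:
        """{formant_index: frequency_hz} for one token (NaN kept)."""
        sub = self.data[self.data["token"] == token]
        if sub.empty:
            raise KeyError(f"unknown token {token!r}")
        return dict(zip(sub["formant_index"], sub["frequency_hz"]))

    def subset(self, mask) -> "FormantTable":
        return FormantTable(self.data[mask], validate=False)

    def for_speaker(self, speaker) -> "FormantTable":
        return self.subset(self.data["speaker"] == speaker)

    def for_group(self, group) -> "FormantTable":
        return self.subset(self.data["group"] == group)

    def with_frequencies(self, freq: np.ndarray) -> "FormantTable":
        """Copy of the table with ``frequency_hz`` replaced (row-aligned)."""
        df = self.data.copy()
        df["frequency_hz"] = np.asarray(freq, dtype=float)
        return FormantTable(df)

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return (
            f"FormantTable({self.n_tokens} tokens, "
            f"{int(self.data['frequency_hz'].notna().sum())} measured formants, "
            f"{len(self.speakers)} speakers)"
        )


def concat_tables(tables: Iterable[FormantTable]) -> FormantTable:
    """Concatenate tables; token ids must remain unique across inputs."""
    df = pd.concat([t.data for t in tables], ignore_index=True)
    return FormantTable(df)
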