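"""Data model and preprocessing for exposome matrices.

An exposome here is a subjects × exposures table of mixed binary / ordinal /
continuous questionnaire variables, each described by a codebook entry:
thematic domain (one of ten), reporter (mother or partner), variable type,
coding direction and feasible range.  This module owns the codebook dialect,
unit-variance standardization, removal of degenerate variables, and the
partner-variable convention (partner-reported answers of subjects without a
partner are set to an arbitrary fill value and flagged through a partner
status indicator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: The ten thematic exposure domains, in their conventional order.
DOMAINS = (
    "personal characteristics",
    "health",
    "development",
    "education",
    "socio-economic",
    "lifestyle",
    "home environment",
    "social environment",
    "life events",
    "chemical and other exposures",
)

VAR_TYPES = ("binary", "ordinal", "continuous")
REPORTERS = ("mother", "partner")

_CODEBOOK_COLUMNS = ["name", "domain", "reporter", "var_type", "direction", "range_low", "range_high"]


@dataclass(frozen=True)
class ExposureVariable:
    """Codebook entry for a single exposure variable.

    ``direction`` is a ±1 multiplier applied at load time so that higher
    values always mean more of (or the presence of) the characteristic.
    ``feasible_range`` is ``(low, high)``; either side may be ``nan`` for an
    unbounded variable.
    """

    name: str
    domain: str
    reporter: str = "mother"
    var_type: str = "continuous"
    direction: int = 1
    feasible_range: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}; must be one of the {len(DOMAINS)} labels")
        if self.reporter not in REPORTERS:
            raise ValueError(f"reporter must be one of {REPORTERS}, got {self.reporter!r}")
        if self.var_type not in VAR_TYPES:
            raise ValueError(f"var_type must be one of {VAR_TYPES}, got {self.var_type!r}")
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")


class Codebook:
    """Immutable collection of :class:`ExposureVariable` entries.

    Stored internally as a DataFrame indexed by variable name; the TSV
    serialization is tab-separated UTF-8 with a header row and columns
    ``name, domain, reporter, var_type, direction, range_low, range_high``.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in _CODEBOOK_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"codebook table lacks columns {missing}")
        table = table[_CODEBOOK_COLUMNS].copy()
        bad = set(table["domain"]) - set(DOMAINS)
        if bad:
            raise ValueError(f"unknown domain labels {sorted(bad)}")
        if not table["direction"].isin([1, -1]).all():
            raise ValueError("directions must be +1 or -1")
        if not table["var_type"].isin(VAR_TYPES).all():
            raise ValueError(f"var_type entries must be one of {VAR_TYPES}")
        if not table["reporter"].isin(REPORTERS).all():
            raise ValueError(f"reporter entries must be one of {REPORTERS}")
        if table["name"].duplicated().any():
            raise ValueError("duplicate variable names in codebook")
        self._table = table.set_index("name", drop=False)

    @classmethod
    def from_variables(cls, variables: list[ExposureVariable]) -> "Codebook":
        rows = [
            {
                "name": v.name,
                "domain": v.domain,
                "reporter": v.reporter,
                "var_type": v.var_type,
                "direction": v.direction,
                "range_low": v.feasible_range[0],
                "range_high": v.feasible_range[1],
            }
            for v in variables
        ]
        return cls(pd.DataFrame(rows, columns=_CODEBOOK_COLUMNS))

    # -- accessors ---------------------------------------------------------
    @property
    def table(self) -> pd.DataFrame:
        return self._table

    @property
    def names(self) -> list[str]:
        return list(self._table.index)

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, name: str) -> bool:
        return name in self._table.index

    def variable(self, name: str) -> ExposureVariable:
        r = self._table.loc[name]
        return ExposureVariable(
            name=r["name"],
            domain=r["domain"],
            reporter=r["reporter"],
            var_type=r["var_type"],
            direction=int(r["direction"]),
            feasible_range=(float(r["range_low"]), float(r["range_high"])),
        )

    def domain_of(self, name: str) -> str:
        return self._table.at[name, "domain"]

    @property
    def partner_variables(self) -> list[str]:
        return list(self._table.index[self._table["reporter"] == "partner"])

    def variables_in_domain(self, domain: str) -> list[str]:
        if domain not in DOMAINS:
            raise ValueError(f"unknown domain {domain!r}")
        return list(self._table.index[self._table["domain"] == domain])

    def subset(self, names: list[str]) -> "Codebook":
        return Codebook(self._table.loc[list(names)].reset_index(drop=True))

    # -- i/o ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self._table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Codebook":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class ExposomeMatrix:
    """Subjects × exposures data with missingness and partner status.

    ``data`` holds float values with ``NaN`` for missing cells; its columns
    must match the codebook names.  ``partner_status`` is 1 for subjects with
    no current partner.  ``convention_mask`` marks cells that were filled by
    the partner-encoding convention rather than genuinely observed; it is
    ``None`` until :func:`encode_partner_variables` runs.
    """

    data: pd.DataFrame
    codebook: Codebook
    partner_status: pd.Series
    convention_mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.data.columns) != self.codebook.names:
            raise ValueError("data columns do not match codebook variable names")
        if not self.data.index.equals(self.partner_status.index):
            raise ValueError("partner_status index does not match data index")
        if self.convention_mask is not None and self.convention_mask.shape != self.data.shape:
            raise ValueError("convention mask shape does not match data")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "ExposomeMatrix":
        return ExposomeMatrix(
            data=self.data.copy(),
            codebook=self.codebook,
            partner_status=self.partner_status.copy(),
            convention_mask=None if self.convention_mask is None else self.convention_mask.copy(),
        )

    def restrict(self, names: list[str]) -> "ExposomeMatrix":
        """Sub-matrix containing only ``names`` (codebook restricted too)."""
        names = list(names)
        return ExposomeMatrix(
            data=self.data[names].copy(),
            codebook=self.codebook.subset(names),
            partner_status=self.partner_status.copy(),
            convention_mask=None if self.convention_mask is None else self.convention_mask[names].copy(),
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "partner_status", self.partner_status)
        out.to_csv(path, sep="\t", index_label="subject")


def read_exposome_tsv(path: str | Path, codebook: Codebook) -> ExposomeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="subject")
    status = df.pop("partner_status").astype(int)
    return ExposomeMatrix(data=df.astype(float), codebook=codebook, partner_status=status)


def apply_coding_directions(matrix: ExposomeMatrix) -> ExposomeMatrix:
    """Multiply each column by its ±1 coding direction.

    After this, higher values always reflect more of the characteristic; the
    codebook directions are reset to +1 so the operation is idempotent.
    """
    dirs = matrix.codebook.table["direction"].to_numpy(float)
    data = matrix.data * dirs[np.newaxis, :]
    table = matrix.codebook.table.copy()
    flipped = table["direction"] == -1
    lo, hi = table["range_low"].copy(), table["range_high"].copy()
    table.loc[flipped, "range_low"] = -hi[flipped]
    table.loc[flipped, "range_high"] = -lo[flipped]
    table["direction"] = 1
    return ExposomeMatrix(
        data=data,
        codebook=Codebook(table.reset_index(drop=True)),
        partner_status=matrix.partner_status,
        convention_mask=matrix.convention_mask,
    )


class DegenerateVariableError(ValueError):
    """A variable is constant where it should vary; drop it with drop_degenerate."""


def standardize(
    matrix: ExposomeMatrix,
    scale_record: pd.Series | None = None,
) -> tuple[ExposomeMatrix, pd.Series]:
    """Scale every column to unit sample variance on its observed entries.

    Means are left in place (the regression intercept absorbs them), matching
    the convention that coefficients are read as outcome units per 1 SD of
    exposure.  The returned ``scale_record`` stores each original SD so that
    raw-scale coefficients can be recovered as ``B_std / SD``; passing a
    previously computed record reuses those frozen scales, which keeps
    coefficients comparable across imputed datasets.

    Raises
    ------
    DegenerateVariableError
        If a column has fewer than two distinct observed values.
    """
    if scale_record is None:
        sds = matrix.data.std(axis=0, ddof=1, skipna=True)
        bad = list(sds.index[~(sds > 0)])  # sd > 0 iff >= 2 distinct observed values
        if bad:
            raise DegenerateVariableError(
                f"{len(bad)} degenerate column(s) (e.g. {bad[:3]}); run drop_degenerate first"
            )
        scale_record = sds.rename("sd")
    else:
        scale_record = scale_record.reindex(matrix.data.columns)
        if scale_record.isna().any():
            raise ValueError("scale record does not cover all columns")
    out = ExposomeMatrix(
        data=matrix.data / scale_record,
        codebook=matrix.codebook,
        partner_status=matrix.partner_status,
        convention_mask=matrix.convention_mask,
    )
    return out, scale_record


def drop_degenerate(
    matrix: ExposomeMatrix, outcome: pd.Series
) -> tuple[ExposomeMatrix, list[str]]:
    """Remove variables constant among subjects with an observed outcome.

    A variable that varies only among outcome-missing subjects carries no
    information for the analysis sample and is dropped along with fully
    constant or fully missing columns.  Returns the reduced matrix and the
    dropped names.
    """
    observed = outcome.notna().to_numpy()
    sub = matrix.data.loc[observed]
    keep = sub.std(axis=0, ddof=1, skipna=True) > 0  # NaN (under 2 observed) -> dropped
    dropped = list(keep.index[~keep])
    if not dropped:
        return matrix, []
    return matrix.restrict(list(keep.index[keep])), dropped


def encode_partner_variables(
    matrix: ExposomeMatrix, fill_value: float = 0.0
) -> ExposomeMatrix:
    """Fill partner-reported variables for partnerless subjects.

    For subjects with ``partner_status == 1`` every partner-reported column is
    set to ``fill_value`` (by default 0, the lowest feasible value).  The
    convention mask records these cells so they are distinguishable from
    genuinely observed values and are never treated as missing by imputation.
    The fill value itself is arbitrary: any model that includes a filled
    partner variable must also include ``partner_status``, and then all other
    coefficients and the fitted values are invariant to the choice.
    """
    out = matrix.copy()
    conv = pd.DataFrame(False, index=matrix.data.index, columns=matrix.data.columns) \
        if matrix.convention_mask is None else out.convention_mask
    partner_vars = matrix.codebook.partner_variables
    partnerless = matrix.partner_status == 1
    if partner_vars and partnerless.any():
        table = matrix.codebook.table
        for name in partner_vars:
            lo, hi = table.at[name, "range_low"], table.at[name, "range_high"]
            if (np.isfinite(lo) and fill_value < lo) or (np.isfinite(hi) and fill_value > hi):
                warnings.warn(
                    f"fill value {fill_value} outside feasible range of {name}; "
                    "the value is arbitrary provided partner_status enters the model",
                    stacklevel=2,
                )
        out.data.loc[partnerless, partner_vars] = fill_value
        conv.loc[partnerless, partner_vars] = True
    out.convention_mask = conv
    return out
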