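"""Bundled chromatographic and computed-lipophilicity data for the
26-compound ipsapirone-derivative library.

Two fixtures ship with the package, stored as plain CSV with the printed
two-decimal values kept verbatim (never re-derived):

* ``table1.csv`` — ten computed octanol/water LogP scales per compound
  (AlvaDesc, Chemicalize and SwissADME families) plus the experimentally
  derived CHI LogP.
* ``table3.csv`` — fast-gradient chromatographic indices: CHI at pH 2.6,
  7.4 and 10.6 on a C18 phase, CHI_IAM on an immobilized-artificial-membrane
  phase, and HSA-column plasma-protein-binding results (logK_HSA, %HSA).

One %HSA cell (compound 18) is censored in the source table; it is parsed
into an explicit censoring marker rather than a guessed value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from ._util import round_half_away

__all__ = [
    "COMPUTED_LOGP_SCALES",
    "CHI_LOGP_SLOPE",
    "CHI_LOGP_INTERCEPT",
    "CompoundRecord",
    "FixtureIntegrityError",
    "load_table1",
    "load_table3",
    "verify_integrity",
    "records_to_frame",
    "write_records",
    "read_records",
]

#: The ten computed-LogP scale names, in fixture column order.
COMPUTED_LOGP_SCALES: tuple[str, ...] = (
    "MLogP",
    "ALogP",
    "LogP99",
    "LogPcons_AlvaDesc",
    "LogP_Chemicalize",
    "iLogP",
    "XLogP3",
    "WLogP",
    "SilicosIT",
    "LogPcons_SwissADME",
)

#: Linear CHI -> CHI LogP map fitted by the source study on nonionized forms.
CHI_LOGP_SLOPE = 0.054
CHI_LOGP_INTERCEPT = -1.467

N_COMPOUNDS = 26

_T1_COLUMNS = ("compound_id", *COMPUTED_LOGP_SCALES, "CHI_LogP")
_T3_COLUMNS = (
    "compound_id",
    "CHI_pH2.6",
    "CHI_pH7.4",
    "CHI_pH10.6",
    "CHI_IAM",
    "LogK_HSA",
    "pct_HSA",
)

_CENSOR_RE = re.compile(r"^\s*[<>]\s*(\d+(?:\.\d+)?)\s*$")


class FixtureIntegrityError(ValueError):
    """A bundled data file failed validation; the message names the cell."""


@dataclass
class CompoundRecord:
    """Chromatographic endpoints and computed LogP values for one compound.

    Chromatographic fields are ``None`` until populated from the
    corresponding table. ``pct_hsa_censored`` marks a percent-HSA value
    reported only as a bound (stored censored-above at the printed bound:
    with logK_HSA = 2.27 the monotone %HSA transform exceeds 100, so the
    printed "<" is treated as a typographical artifact and the direction
    is "greater").
    """

    compound_id: int
    chi_acid: float | None = None  # CHI, C18 phase, pH 2.6
    chi_neutral: float | None = None  # CHI, C18 phase, pH 7.4
    chi_basic: float | None = None  # CHI, C18 phase, pH 10.6
    chi_iam: float | None = None  # CHI_IAM, pH 7.4
    logk_hsa: float | None = None
    pct_hsa: float | None = None
    pct_hsa_censored: bool = False
    computed_logp: dict[str, float] = field(default_factory=dict)
    chi_logp: float | None = None


def _data_path(name: str) -> Path:
    return Path(str(resources.files("lipichrom") / "data" / name))


def _read_fixture(path: Path, expected_columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    if tuple(df.columns) != expected_columns:
        raise FixtureIntegrityError(
            f"{path.name}: header {tuple(df.columns)!r} != {expected_columns!r}"
        )
    return df


def _parse_float(path_name: str, row: int, col: str, raw: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise FixtureIntegrityError(
            f"{path_name}: cell (row {row}, column {col!r}) is not numeric: {raw!r}"
        ) from None


def load_table1(path: str | Path | None = None) -> list[CompoundRecord]:
    """Load the computed-LogP table (ten scales plus CHI LogP).

    Returns the 26 compounds in order, with ``computed_logp`` and
    ``chi_logp`` populated. Raises :class:`FixtureIntegrityError` naming the
    offending cell if the file is corrupt.
    """
    p = Path(path) if path is not None else _data_path("table1.csv")
    df = _read_fixture(p, _T1_COLUMNS)
    records = []
    for i, row in df.iterrows():
        cid = int(_parse_float(p.name, i + 1, "compound_id", row["compound_id"]))
        rec = CompoundRecord(compound_id=cid)
        for scale in COMPUTED_LOGP_SCALES:
            rec.computed_logp[scale] = _parse_float(p.name, cid, scale, row[scale])
        rec.chi_logp = _parse_float(p.name, cid, "CHI_LogP", row["CHI_LogP"])
        records.append(rec)
    _check_shape(records, p.name)
    return records


def load_table3(path: str | Path | None = None) -> list[CompoundRecord]:
    """Load the chromatographic/biochromatographic index table.

    Returns the 26 compounds with CHI (three pH values), CHI_IAM, logK_HSA
    and %HSA populated; censored %HSA cells carry ``pct_hsa_censored=True``.
    """
    p = Path(path) if path is not None else _data_path("table3.csv")
    df = _read_fixture(p, _T3_COLUMNS)
    records = []
    for i, row in df.iterrows():
        cid = int(_parse_float(p.name, i + 1, "compound_id", row["compound_id"]))
        raw_pct = row["pct_HSA"]
        m = _CENSOR_RE.match(str(raw_pct))
        if m:
            pct, censored = float(m.group(1)), True
        else:
            pct, censored = _parse_float(p.name, cid, "pct_HSA", raw_pct), False
        records.append(
            CompoundRecord(
                compound_id=cid,
                chi_acid=_parse_float(p.name, cid, "CHI_pH2.6", row["CHI_pH2.6"]),
                chi_neutral=_parse_float(p.name, cid, "CHI_pH7.4", row["CHI_pH7.4"]),
                chi_basic=_parse_float(p.name, cid, "CHI_pH10.6", row["CHI_pH10.6"]),
                chi_iam=_parse_float(p.name, cid, "CHI_IAM", row["CHI_IAM"]),
                logk_hsa=_parse_float(p.name, cid, "LogK_HSA", row["LogK_HSA"]),
                pct_hsa=pct,
                pct_hsa_censored=censored,
            )
        )
    _check_shape(records, p.name)
    return records


def _check_shape(records: list[CompoundRecord], name: str) -> None:
    if len(records) != N_COMPOUNDS:
        raise FixtureIntegrityError(f"{name}: expected {N_COMPOUNDS} rows, got {len(records)}")
    ids = [r.compound_id for r in records]
    if ids != list(range(1, N_COMPOUNDS + 1)):
        raise FixtureIntegrityError(f"{name}: compound_id column is not 1..{N_COMPOUNDS}")


@dataclass
class IntegrityReport:
    """Per-row result of the CHI LogP cross-table consistency check."""

    rows: list[dict]

    @property
    def n_pass(self) -> int:
        return sum(r["ok"] for r in self.rows)

    @property
    def all_ok(self) -> bool:
        return all(r["ok"] for r in self.rows)

    def failures(self) -> list[dict]:
        return [r for r in self.rows if not r["ok"]]


def verify_integrity(
    records_t1: list[CompoundRecord], records_t3: list[CompoundRecord]
) -> IntegrityReport:
    """Check that CHI LogP equals 0.054*CHI(pH 10.6) - 1.467 row by row.

    The computed-LogP table carries the converted value and the index table
    the underlying CHI at pH 10.6; recomputing the linear map (rounded to
    2 decimals, half away from zero) must reproduce the printed column.
    """
    rows = []
    for r1, r3 in zip(records_t1, records_t3):
        expected = round_half_away(CHI_LOGP_SLOPE * r3.chi_basic + CHI_LOGP_INTERCEPT, 2)
        rows.append(
            {
                "compound_id": r1.compound_id,
                "chi_basic": r3.chi_basic,
                "recomputed": expected,
                "printed": r1.chi_logp,
                "ok": expected == r1.chi_logp,
            }
        )
    return IntegrityReport(rows)


def records_to_frame(records: list[CompoundRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame indexed by compound_id (all
    populated fields become columns; computed LogP scales keep their names)."""
    rows = {}
    for r in records:
        d: dict[str, object] = {}
        for attr, col in [
            ("chi_acid", "CHI_pH2.6"),
            ("chi_neutral", "CHI_pH7.4"),
            ("chi_basic", "CHI_pH10.6"),
            ("chi_iam", "CHI_IAM"),
            ("logk_hsa", "LogK_HSA"),
        ]:
            v = getattr(r, attr)
            if v is not None:
                d[col] = v
        if r.pct_hsa is not None:
            d["pct_HSA"] = f"<{r.pct_hsa:.2f}" if r.pct_hsa_censored else r.pct_hsa
        d.update(r.computed_logp)
        if r.chi_logp is not None:
            d["CHI_LogP"] = r.chi_logp
        rows[r.compound_id] = d
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "compound_id"
    return out


def write_records(records: list[CompoundRecord], path: str | Path) -> None:
    """Write records as CSV with two-decimal formatting (lossless for the
    bundled fixtures, which are two-decimal by construction)."""
    frame = records_to_frame(records)

    def _fmt(v: object) -> object:
        return f"{v:.2f}" if isinstance(v, float) else v

    frame.map(_fmt).to_csv(path)


def read_records(path: str | Path) -> list[CompoundRecord]:
    """Read a CSV produced by :func:`write_records` back into records."""
    df = pd.read_csv(path, dtype=str).set_index("compound_id")
    records = []
    for cid, row in df.iterrows():
        rec = CompoundRecord(compound_id=int(cid))
        for col, raw in row.items():
            if pd.isna(raw):
                continue
            if col == "pct_HSA":
                m = _CENSOR_RE.match(str(raw))
                if m:
                    rec.pct_hsa, rec.pct_hsa_censored = float(m.group(1)), True
                else:
                    rec.pct_hsa = float(raw)
            elif col in COMPUTED_LOGP_SCALES:
                rec.computed_logp[col] = float(raw)
            else:
                attr = {
                    "CHI_pH2.6": "chi_acid",
                    "CHI_pH7.4": "chi_neutral",
                    "CHI_pH10.6": "chi_basic",
                    "CHI_IAM": "chi_iam",
                    "LogK_HSA": "logk_hsa",
                    "CHI_LogP": "chi_logp",
                }[col]
                setattr(rec, attr, float(raw))
        records.append(rec)
    return records
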