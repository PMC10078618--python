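"""Bundled fixtures, delimited-text I/O and run manifests.

All tabular I/O is comma-separated UTF-8 text with ``#`` comment lines; any
Unicode minus signs (U+2212) in hand-pasted inputs are normalized to ASCII
on read.  Configuration files are YAML.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .budget import BudgetResult, TreatmentBudgetInputs, budget_frame
from .core import ForcingSeries
from .exceptions import IntegrityError, InvalidInputError
from .response import ResponseCoefficients
from .scenarios import ScenarioSpec

__all__ = [
    "FixtureSet",
    "RunManifest",
    "load_fixtures",
    "read_treatments",
    "read_forcing",
    "write_budget",
    "read_scenario_spec",
    "read_model_config",
]

_FORCING_COLUMNS = ("day", "anpp", "bnpp", "f_ch4", "sal")

_MINUS_SIGN = "−"


def _read_csv(source) -> pd.DataFrame:
    """Read a comment-tolerant CSV, normalizing Unicode minus signs."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    text = text.replace(_MINUS_SIGN, "-")
    return pd.read_csv(_io.StringIO(text), comment="#")


@dataclass(frozen=True)
class FixtureSet:
    """The bundled treatment records, rate table and default coefficients."""

    treatments: tuple[TreatmentBudgetInputs, ...]
    rates: pd.DataFrame = field(repr=False)
    coefficients: ResponseCoefficients = field(repr=False)
    scenario_defaults: ScenarioSpec = field(repr=False)

    def treatment(self, treatment_id: str) -> TreatmentBudgetInputs:
        for rec in self.treatments:
            if rec.treatment_id == treatment_id:
                return rec
        raise KeyError(treatment_id)

    def rates_for(self, treatment_id: str) -> dict:
        match = self.rates[self.rates["treatment_id"] == treatment_id]
        if match.empty:
            raise KeyError(treatment_id)
        return match.iloc[0].to_dict()


def read_treatments(source) -> list[TreatmentBudgetInputs]:
    """Parse a treatments CSV into validated budget-input records."""
    frame = _read_csv(source)
    required = {
        "treatment_id", "anpp", "bnpp", "d_ag", "d_bg", "nee", "f_ch4",
        "delta_pd_cm", "rho_b_field", "rho_b_exp", "f_c", "alpha",
    }
    missing = required - set(frame.columns)
    if missing:
        raise InvalidInputError(f"treatments file missing columns: {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            TreatmentBudgetInputs(
                treatment_id=str(row["treatment_id"]),
                anpp=float(row["anpp"]),
                bnpp=float(row["bnpp"]),
                d_ag=float(row["d_ag"]),
                d_bg=float(row["d_bg"]),
                nee=float(row["nee"]),
                f_ch4=float(row["f_ch4"]),
                delta_pd_cm=float(row["delta_pd_cm"]),
                rho_b_field=float(row["rho_b_field"]),
                rho_b_exp=float(row["rho_b_exp"]),
                f_c=float(row["f_c"]),
                alpha=float(row["alpha"]),
            )
        )
    return records


def load_fixtures() -> FixtureSet:
    """Load and validate the bundled fixture set (pure; no mutation)."""
    data = resources.files("evpem.data")
    try:
        treatments = read_treatments(
            _io.StringIO(data.joinpath("treatments.csv").read_text(encoding="utf-8"))
        )
        rates = _read_csv(
            _io.StringIO(data.joinpath("treatment_rates.csv").read_text(encoding="utf-8"))
        )
        coefficients = ResponseCoefficients.default()
    except (InvalidInputError, KeyError, FileNotFoundError) as exc:
        raise IntegrityError(f"bundled fixtures failed validation: {exc}") from exc
    if len(treatments) != 7:
        raise IntegrityError(f"expected 7 bundled treatments, found {len(treatments)}")
    ids = {t.treatment_id for t in treatments}
    if ids != set(rates["treatment_id"]):
        raise IntegrityError("treatment ids differ between treatments.csv and treatment_rates.csv")
    return FixtureSet(
        treatments=tuple(treatments),
        rates=rates,
        coefficients=coefficients,
        scenario_defaults=ScenarioSpec(),
    )


def read_forcing(source, units_mode: str = "daily") -> ForcingSeries:
    """Read a daily forcing CSV into a :class:`ForcingSeries`.

    The file must have columns day, anpp, bnpp, f_ch4, sal and either wl or
    slr.  With ``units_mode="annual"`` the flux columns are annual totals and
    are divided by 365 on load.
    """
    frame = _read_csv(source)
    missing = set(_FORCING_COLUMNS) - set(frame.columns)
    if missing:
        raise InvalidInputError(f"forcing file missing columns: {sorted(missing)}")
    has_wl = "wl" in frame.columns
    has_slr = "slr" in frame.columns
    if has_wl == has_slr:
        raise InvalidInputError("forcing file must have exactly one of wl or slr")
    nan_rows = frame[list(_FORCING_COLUMNS[1:]) + (["wl"] if has_wl else ["slr"])].isna()
    if nan_rows.any().any():
        row = int(nan_rows.any(axis=1).idxmax())
        raise InvalidInputError(f"missing value in forcing file at row {row}")
    kwargs = dict(
        anpp=frame["anpp"].to_numpy(float),
        bnpp=frame["bnpp"].to_numpy(float),
        f_ch4=frame["f_ch4"].to_numpy(float),
        sal=frame["sal"].to_numpy(float),
        wl=frame["wl"].to_numpy(float) if has_wl else None,
        slr=frame["slr"].to_numpy(float) if has_slr else None,
    )
    if units_mode == "annual":
        return ForcingSeries.from_annual(**kwargs)
    if units_mode != "daily":
        raise InvalidInputError(f"units_mode must be 'daily' or 'annual', got {units_mode!r}")
    return ForcingSeries(**kwargs)


def write_budget(results: Sequence[BudgetResult], path) -> None:
    """Write budget results to CSV with the documented column order."""
    budget_frame(results).to_csv(path, index=False)


def read_scenario_spec(path) -> ScenarioSpec:
    """Read a scenario YAML mirroring :class:`ScenarioSpec` field names."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("season_months", "season_depths"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        return ScenarioSpec(**raw)
    except TypeError as exc:
        raise InvalidInputError(f"unknown scenario field: {exc}") from exc


def read_model_config(path):
    """Read a simulation config YAML mirroring ModelConfig field names."""
    from .core import ModelConfig

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return ModelConfig(**raw)
    except TypeError as exc:
        raise InvalidInputError(f"unknown config field: {exc}") from exc


@dataclass
class RunManifest:
    """Provenance record written as run.json next to every CLI output."""

    command: str
    inputs: dict
    seed: int | None = None
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S%z")

    @staticmethod
    def checksum(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    @classmethod
    def for_run(cls, command: str, input_paths: dict, seed: int | None = None) -> "RunManifest":
        inputs = {
            name: {"path": str(p), "sha256": cls.checksum(p)}
            for name, p in input_paths.items()
            if p is not None
        }
        return cls(command=command, inputs=inputs, seed=seed)

    def write(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / "run.json"
        path.write_text(
            json.dumps(
                {
                    "command": self.command,
                    "inputs": self.inputs,
                    "seed": self.seed,
                    "version": self.version,
                    "timestamp": self.timestamp,
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )
        return path
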