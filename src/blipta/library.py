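"""Typed model library: population-PK models, dose regimens, site penetration and
PK/PD targets, with YAML file I/O.

This module is the single source of truth for every symbol used downstream:

* :class:`PopPKModel` -- linear mamillary compartmental model (1-3 compartments)
  with typical parameters, log-normal interindividual variability (IIV) and a
  creatinine-clearance covariate relation on clearance.
* :class:`DoseRegimen` -- intermittent constant-rate intravenous infusions.
* :class:`SitePenetration` -- unbound fraction (fu) and tissue penetration ratios
  (TPR) per infection site, with optional low/high bounds for sensitivity sweeps
  and a provenance flag (measured / extrapolated).
* :class:`PKPDTarget` -- the pharmacodynamic index (%fT>MIC, %fT>C_T or
  fAUC0-24/MIC) and its tier magnitudes (EUCAST < Severe < Aggressive).
* :class:`CombinationSpec` -- a BL/BLI pair with per-indication regimens and a
  shared MIC grid.

Units are fixed throughout: mg, L, h, mg/L for concentrations and MIC,
mL/min for creatinine clearance.
"""

from __future__ import annotations

import copy
import math
import pathlib
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import LibraryError, UnknownPenetrationError

Site = Literal["plasma", "ELF", "peritoneal", "prostate"]
Tier = Literal["EUCAST", "Severe", "Aggressive"]
MetricKind = Literal["ft_above_mic", "ft_above_ct", "fauc_over_mic"]

SITES: tuple[str, ...] = ("plasma", "ELF", "peritoneal", "prostate")
TIER_ORDER: tuple[str, ...] = ("EUCAST", "Severe", "Aggressive")
INDICATIONS: tuple[str, ...] = ("cIAI", "HAP/VAP", "cUTI", "bacteraemia", "prostatitis")

#: Fixed mapping from therapeutic indication to the infection-site matrix whose
#: unbound concentration drives target attainment.
INDICATION_SITE: dict[str, str] = {
    "cIAI": "peritoneal",
    "HAP/VAP": "ELF",
    "cUTI": "plasma",
    "bacteraemia": "plasma",
    "prostatitis": "prostate",
}

_REQUIRED_PARAMS = {
    1: ("CL", "V1"),
    2: ("CL", "V1", "Q2", "V2"),
    3: ("CL", "V1", "Q2", "V2", "Q3", "V3"),
}


class PatientScenario(BaseModel):
    """A renal-function scenario: every virtual patient shares this covariate set.

    Covariates other than creatinine clearance are frozen at each source model's
    reference value, so CrCL is the only dimension simulated.
    """

    model_config = ConfigDict(frozen=True)

    label: str
    crcl_mL_per_min: float = Field(gt=0)


#: Typical renal clearance (TRC) and augmented renal clearance (ARC) populations.
SCENARIOS: dict[str, PatientScenario] = {
    "TRC": PatientScenario(label="TRC", crcl_mL_per_min=80.0),
    "ARC": PatientScenario(label="ARC", crcl_mL_per_min=200.0),
}


class CovariateRelation(BaseModel):
    """Multiplicative covariate effect on one structural parameter.

    ``power``         multiplier = (value / reference) ** exponent_or_slope
    ``linear``        multiplier = 1 + exponent_or_slope * (value - reference)
    ``proportional``  multiplier = value / reference

    ``covariate_cap`` optionally truncates the covariate before evaluation
    (a CrCL ceiling declared by a source model). At the reference value the
    multiplier is exactly 1 by construction.
    """

    parameter: str
    covariate: str = "CRCL"
    form: Literal["power", "linear", "proportional"]
    reference_value: float = Field(gt=0)
    exponent_or_slope: float = 1.0
    covariate_cap: Optional[float] = Field(default=None, gt=0)


def covariate_multiplier(rel: CovariateRelation, covariate_value: float) -> float:
    """Evaluate a covariate relation; strictly positive result guaranteed."""
    if covariate_value <= 0:
        raise LibraryError(
            f"covariate {rel.covariate} must be positive, got {covariate_value}",
            field=rel.parameter,
        )
    v = covariate_value
    if rel.covariate_cap is not None:
        v = min(v, rel.covariate_cap)
    if rel.form == "power":
        return (v / rel.reference_value) ** rel.exponent_or_slope
    if rel.form == "proportional":
        return v / rel.reference_value
    mult = 1.0 + rel.exponent_or_slope * (v - rel.reference_value)
    if mult <= 0:
        raise LibraryError(
            f"linear covariate relation on {rel.parameter} yields non-positive "
            f"multiplier {mult:.4g} at {rel.covariate}={covariate_value}",
            field=rel.parameter,
        )
    return mult


class IIVSpec(BaseModel):
    """Log-scale interindividual variability over a declared parameter subset."""

    parameters: list[str] = Field(default_factory=list)
    matrix: list[list[float]] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "IIVSpec":
        k = len(self.parameters)
        if len(self.matrix) != k or any(len(row) != k for row in self.matrix):
            raise ValueError("iiv matrix shape must match the declared parameter list")
        if k:
            m = np.asarray(self.matrix, dtype=float)
            if not np.allclose(m, m.T, atol=1e-12):
                raise ValueError("iiv covariance matrix must be symmetric")
            eig = np.linalg.eigvalsh(m)
            if eig.min() < -1e-10:
                raise ValueError(
                    f"iiv covariance matrix is not positive semi-definite "
                    f"(min eigenvalue {eig.min():.3g})"
                )
        return self

    def covariance(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float).reshape(
            len(self.parameters), len(self.parameters)
        )


class PopPKModel(BaseModel):
    """Linear mamillary compartmental model with log-normal IIV.

    ``typical_params`` holds CL (L/h), V1/V2/V3 (L) and inter-compartmental
    clearances Q2/Q3 (L/h); the set of V/Q keys must match ``n_compartments``
    exactly. Individual parameters are
    ``typical * covariate multiplier * exp(eta)`` with
    ``eta ~ MVN(0, iiv covariance)``.
    """

    compound_name: str
    n_compartments: int = Field(ge=1, le=3)
    typical_params: dict[str, float]
    iiv: IIVSpec = Field(default_factory=IIVSpec)
    covariate_relations: list[CovariateRelation] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "PopPKModel":
        required = set(_REQUIRED_PARAMS[self.n_compartments])
        present = set(self.typical_params)
        if present != required:
            missing = required - present
            extra = present - required
            bits = []
            if missing:
                bits.append(f"missing {sorted(missing)}")
            if extra:
                bits.append(f"unexpected {sorted(extra)}")
            raise ValueError(
                f"{self.n_compartments}-compartment model parameter set mismatch: "
                + "; ".join(bits)
            )
        for name, value in self.typical_params.items():
            if not (value > 0) or not math.isfinite(value):
                raise ValueError(f"typical parameter {name} must be strictly positive")
        for p in self.iiv.parameters:
            if p not in self.typical_params:
                raise ValueError(f"iiv references undeclared parameter {p!r}")
        for rel in self.covariate_relations:
            if rel.parameter not in self.typical_params:
                raise ValueError(
                    f"covariate relation references undeclared parameter {rel.parameter!r}"
                )
        return self

    def adjusted_typicals(self, scenario: PatientScenario) -> dict[str, float]:
        """Typical parameters scaled by every covariate multiplier of the scenario.

        Only CrCL varies between scenarios; any other covariate in a relation is
        taken at its reference value (multiplier 1).
        """
        values = dict(self.typical_params)
        for rel in self.covariate_relations:
            if rel.covariate.upper() in ("CRCL", "CREATININE_CLEARANCE"):
                cov = scenario.crcl_mL_per_min
            else:  # frozen at reference -> multiplier 1
                cov = rel.reference_value
            values[rel.parameter] *= covariate_multiplier(rel, cov)
        return values


class DoseRegimen(BaseModel):
    """Intermittent constant-rate infusion: dose_mg over infusion_duration_h,
    repeated every interval_h."""

    model_config = ConfigDict(frozen=True)

    dose_mg: float = Field(gt=0)
    infusion_duration_h: float = Field(gt=0)
    interval_h: float = Field(gt=0)
    n_doses_to_steady_state: Optional[int] = Field(default=None, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "DoseRegimen":
        if self.infusion_duration_h > self.interval_h:
            raise ValueError("infusion_duration_h must not exceed interval_h")
        return self


class TPREntry(BaseModel):
    """One site's tissue penetration ratio with bounds and provenance.

    ``low``/``high`` default to the point value when the source gives no range;
    ``bounded`` records whether a real range was declared (the sensitivity sweep
    warns and falls back to base otherwise).
    """

    value: float = Field(gt=0, le=1.3)
    low: Optional[float] = Field(default=None, gt=0, le=1.3)
    high: Optional[float] = Field(default=None, gt=0, le=1.3)
    provenance: Literal["measured", "extrapolated", "unknown", "definition"] = "measured"

    @model_validator(mode="after")
    def _check(self) -> "TPREntry":
        if (self.low is None) != (self.high is None):
            raise ValueError("low and high bounds must be given together")
        if self.low is not None and not (self.low <= self.value <= self.high):
            raise ValueError("TPR bounds must satisfy low <= value <= high")
        return self

    @property
    def bounded(self) -> bool:
        return self.low is not None

    def pick(self, which: str) -> float:
        if which == "base":
            return self.value
        if not self.bounded:
            raise KeyError("no bounds declared")
        return self.low if which == "low" else self.high


class SitePenetration(BaseModel):
    """Unbound fraction in plasma and per-site penetration ratios.

    The ``plasma`` site always carries TPR = 1 by definition (unbound plasma is
    the reference matrix); it is inserted automatically.
    """

    compound_name: str
    fu: float = Field(gt=0, le=1)
    fu_low: Optional[float] = Field(default=None, gt=0, le=1)
    fu_high: Optional[float] = Field(default=None, gt=0, le=1)
    tpr: dict[Site, TPREntry] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "SitePenetration":
        if (self.fu_low is None) != (self.fu_high is None):
            raise ValueError("fu_low and fu_high must be given together")
        if self.fu_low is not None and not (self.fu_low <= self.fu <= self.fu_high):
            raise ValueError("fu bounds must satisfy low <= value <= high")
        plasma = self.tpr.get("plasma")
        if plasma is not None and plasma.value != 1.0:
            raise ValueError("plasma TPR is 1 by definition")
        if plasma is None:
            self.tpr["plasma"] = TPREntry(value=1.0, low=1.0, high=1.0, provenance="definition")
        return self

    @property
    def fu_bounded(self) -> bool:
        return self.fu_low is not None

    def pick_fu(self, which: str) -> float:
        if which == "base":
            return self.fu
        if not self.fu_bounded:
            raise KeyError("no fu bounds declared")
        return self.fu_low if which == "low" else self.fu_high

    def resolve(self, site: str) -> TPREntry:
        """Return the TPR entry for ``site`` or raise :class:`UnknownPenetrationError`."""
        entry = self.tpr.get(site)
        if entry is None or entry.provenance == "unknown":
            raise UnknownPenetrationError(
                f"no penetration ratio for {self.compound_name} at site {site!r}"
            )
        return entry


class PKPDTarget(BaseModel):
    """A PK/PD index with its three tier magnitudes.

    Time metrics (%fT>MIC, %fT>C_T) are expressed as percent of the dosing
    interval in (0, 100]; fAUC0-24/MIC magnitudes are dimensionless ratios.
    Tier magnitudes must be strictly increasing EUCAST < Severe < Aggressive.
    """

    metric: MetricKind
    tier_magnitudes: dict[Tier, float]
    c_t_mg_per_L: float = Field(default=1.0, gt=0)
    mic_grid_mg_per_L: list[float] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "PKPDTarget":
        if set(self.tier_magnitudes) != set(TIER_ORDER):
            raise ValueError(f"tier magnitudes must cover exactly {TIER_ORDER}")
        mags = [self.tier_magnitudes[t] for t in TIER_ORDER]
        if not (mags[0] < mags[1] < mags[2]):
            raise ValueError(
                "tier magnitudes must be strictly increasing EUCAST < Severe < Aggressive"
            )
        if self.metric in ("ft_above_mic", "ft_above_ct"):
            if not all(0 < m <= 100 for m in mags):
                raise ValueError("time-metric magnitudes must lie in (0, 100]")
        if any(m <= 0 for m in self.mic_grid_mg_per_L):
            raise ValueError("MIC values must be positive")
        if any(
            b <= a for a, b in zip(self.mic_grid_mg_per_L, self.mic_grid_mg_per_L[1:])
        ):
            raise ValueError("MIC grid must be strictly increasing")
        return self

    def magnitude(self, tier: str) -> float:
        return self.tier_magnitudes[tier]


class CompoundEntry(BaseModel):
    """One compound's model + penetration + target, keyed by library entry name.

    ``key`` may differ from ``compound_name`` when a compound appears with
    combination-specific parameters (e.g. tazobactam with ceftolozane vs with
    piperacillin).
    """

    key: str
    model: PopPKModel
    penetration: SitePenetration
    target: PKPDTarget


class ComboRegimen(BaseModel):
    bl: DoseRegimen
    bli: DoseRegimen


class CombinationSpec(BaseModel):
    """A BL/BLI pair, its per-indication SmPC regimens and the shared MIC grid."""

    name: str
    bl: CompoundEntry
    bli: CompoundEntry
    regimens: dict[str, ComboRegimen]
    mic_grid_mg_per_L: list[float]
    co_formulated: bool = True
    prostatitis_from: str = "cUTI"

    @model_validator(mode="after")
    def _check(self) -> "CombinationSpec":
        for ind in self.regimens:
            if ind not in INDICATIONS:
                raise ValueError(f"unknown indication {ind!r}")
        if self.co_formulated:
            for ind, reg in self.regimens.items():
                if (
                    reg.bl.interval_h != reg.bli.interval_h
                    or reg.bl.infusion_duration_h != reg.bli.infusion_duration_h
                ):
                    raise ValueError(
                        f"co-formulated combination must share interval and infusion "
                        f"duration ({ind})"
                    )
        if not self.mic_grid_mg_per_L:
            raise ValueError("MIC grid must be non-empty")
        return self

    def component(self, which: str) -> CompoundEntry:
        if which == "BL":
            return self.bl
        if which == "BLI":
            return self.bli
        raise KeyError(f"component must be 'BL' or 'BLI', got {which!r}")

    def regimen_for(self, indication: str, which: str) -> DoseRegimen:
        reg = self.regimens.get(indication)
        if reg is None:
            raise LibraryError(
                f"combination {self.name} declares no regimen for {indication!r}",
                field="regimens",
            )
        return reg.bl if which == "BL" else reg.bli


class ModelLibrary(BaseModel):
    """Validated set of compounds and combinations loaded from a config directory."""

    compounds: dict[str, CompoundEntry]
    combinations: dict[str, CombinationSpec]

    def combination(self, name: str) -> CombinationSpec:
        try:
            return self.combinations[name]
        except KeyError:
            raise LibraryError(f"unknown combination {name!r}") from None


# ---------------------------------------------------------------------------
# File I/O


def _load_yaml(path: pathlib.Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise LibraryError("config file must contain a mapping", source=path.name)
    return doc


def _compound_from_doc(doc: dict, source: str) -> CompoundEntry:
    try:
        name = doc["compound_name"]
        return CompoundEntry(
            key=doc.get("key", name),
            model=PopPKModel(compound_name=name, **doc["model"]),
            penetration=SitePenetration(compound_name=name, **doc.get("penetration", {})),
            target=PKPDTarget(**doc["target"]),
        )
    except (KeyError, ValueError) as exc:
        raise LibraryError(str(exc), source=source) from exc


def _swap_tpr(a: SitePenetration, b: SitePenetration, sites: tuple[str, ...]) -> None:
    for site in sites:
        ea, eb = a.tpr.get(site), b.tpr.get(site)
        if ea is not None and eb is not None:
            a.tpr[site], b.tpr[site] = eb, ea


def _build_combination(doc: dict, compounds: dict[str, CompoundEntry], source: str) -> CombinationSpec:
    try:
        bl = copy.deepcopy(compounds[doc["bl"]])
        bli = copy.deepcopy(compounds[doc["bli"]])
    except KeyError as exc:
        raise LibraryError(f"combination references unknown compound {exc}", source=source)
    mic_grid = [float(m) for m in doc["mic_grid_mg_per_L"]]
    bl.target = bl.target.model_copy(update={"mic_grid_mg_per_L": mic_grid})
    bli.target = bli.target.model_copy(update={"mic_grid_mg_per_L": mic_grid})

    regimens = {
        ind: ComboRegimen(bl=DoseRegimen(**reg["bl"]), bli=DoseRegimen(**reg["bli"]))
        for ind, reg in doc["regimens"].items()
    }
    prost_from = doc.get("prostatitis_from", "cUTI")
    if "prostatitis" not in regimens and prost_from in regimens:
        # prostatitis has no SmPC regimen of its own; reuse the configured source
        regimens["prostatitis"] = regimens[prost_from]

    # BL -> BLI extrapolation rule: a BLI missing a TPR inherits the BL's value.
    for site in ("ELF", "peritoneal", "prostate"):
        if site not in bli.penetration.tpr and site in bl.penetration.tpr:
            src = bl.penetration.tpr[site]
            if src.provenance != "unknown":
                bli.penetration.tpr[site] = src.model_copy(
                    update={"provenance": "extrapolated"}
                )

    try:
        combo = CombinationSpec(
            name=doc["name"],
            bl=bl,
            bli=bli,
            regimens=regimens,
            mic_grid_mg_per_L=mic_grid,
            co_formulated=doc.get("co_formulated", True),
            prostatitis_from=prost_from,
        )
    except (KeyError, ValueError) as exc:
        raise LibraryError(str(exc), source=source) from exc

    # Every explicitly declared indication must resolve a site TPR for both
    # components (prostatitis is implicit and may legitimately be unresolvable).
    for ind in doc["regimens"]:
        site = INDICATION_SITE[ind]
        for entry in (combo.bl, combo.bli):
            try:
                entry.penetration.resolve(site)
            except UnknownPenetrationError as exc:
                raise LibraryError(
                    f"declared indication {ind!r} needs site {site!r}: {exc}",
                    source=source,
                ) from exc
    return combo


def load_model_library(
    path: str | pathlib.Path,
    *,
    swap_tpr_between: tuple[str, str] | None = None,
) -> ModelLibrary:
    """Load and validate every ``*.yaml`` config file under ``path``.

    ``swap_tpr_between`` exchanges the ELF and peritoneal TPR entries between the
    two named compound keys before combinations are assembled (the supplementary
    tazobactam CET-TAZ/PIP-TAZ swap analysis).
    """
    path = pathlib.Path(path)
    files = sorted(path.glob("*.yaml"))
    if not files:
        raise LibraryError(f"no config files found under {path}")
    compound_docs, combo_docs = [], []
    for f in files:
        doc = _load_yaml(f)
        kind = doc.get("kind")
        if kind == "compound":
            compound_docs.append((doc, f.name))
        elif kind == "combination":
            combo_docs.append((doc, f.name))
        else:
            raise LibraryError(
                f"kind must be 'compound' or 'combination', got {kind!r}", source=f.name
            )
    compounds: dict[str, CompoundEntry] = {}
    for doc, src in compound_docs:
        entry = _compound_from_doc(doc, src)
        if entry.key in compounds:
            raise LibraryError(f"duplicate compound key {entry.key!r}", source=src)
        compounds[entry.key] = entry
    if swap_tpr_between is not None:
        a, b = swap_tpr_between
        try:
            _swap_tpr(
                compounds[a].penetration, compounds[b].penetration, ("ELF", "peritoneal")
            )
        except KeyError as exc:
            raise LibraryError(f"swap references unknown compound {exc}")
    combinations: dict[str, CombinationSpec] = {}
    for doc, src in combo_docs:
        combo = _build_combination(doc, compounds, src)
        combinations[combo.name] = combo
    return ModelLibrary(compounds=compounds, combinations=combinations)


def _compound_to_doc(entry: CompoundEntry) -> dict:
    model = entry.model
    doc = {
        "kind": "compound",
        "key": entry.key,
        "compound_name": model.compound_name,
        "model": {
            "n_compartments": model.n_compartments,
            "typical_params": dict(model.typical_params),
            "iiv": {
                "parameters": list(model.iiv.parameters),
                "matrix": [list(r) for r in model.iiv.matrix],
            },
            "covariate_relations": [
                r.model_dump(exclude_none=True) for r in model.covariate_relations
            ],
        },
        "penetration": entry.penetration.model_dump(
            exclude={"compound_name"}, exclude_none=True
        ),
        "target": entry.target.model_dump(exclude_none=True),
    }
    return doc


def _combination_to_doc(combo: CombinationSpec) -> dict:
    return {
        "kind": "combination",
        "name": combo.name,
        "bl": combo.bl.key,
        "bli": combo.bli.key,
        "co_formulated": combo.co_formulated,
        "prostatitis_from": combo.prostatitis_from,
        "mic_grid_mg_per_L": list(combo.mic_grid_mg_per_L),
        "regimens": {
            ind: {
                "bl": reg.bl.model_dump(exclude_none=True),
                "bli": reg.bli.model_dump(exclude_none=True),
            }
            for ind, reg in combo.regimens.items()
        },
    }


def write_library(library: ModelLibrary, path: str | pathlib.Path) -> None:
    """Write the library back to one YAML file per compound/combination.

    Floats are emitted with full repr precision so a load/write/load round trip
    reproduces every numeric field bit-exactly.
    """
    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for key, entry in library.compounds.items():
        with open(path / f"{key}.yaml", "w") as fh:
            yaml.safe_dump(_compound_to_doc(entry), fh, sort_keys=True)
    for name, combo in library.combinations.items():
        fname = name.lower().replace("/", "_").replace("-", "_")
        with open(path / f"{fname}.yaml", "w") as fh:
            yaml.safe_dump(_combination_to_doc(combo), fh, sort_keys=True)


def default_library_path() -> pathlib.Path:
    """Directory of the transcribed compound/combination configs shipped with the package."""
    return pathlib.Path(__file__).parent / "data" / "library"


def synthetic_library_path() -> pathlib.Path:
    """Directory of the self-contained synthetic fixture configs."""
    return pathlib.Path(__file__).parent / "data" / "synthetic"
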