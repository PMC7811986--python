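"""Frequency-dependent dielectric properties of body tissues.

Below 1 MHz a tissue is characterised by its conductivity sigma(f) [S/m] and
relative permittivity eps_r(f).  Both enter the electro-quasi-static solver
only through the complex conductivity

    sigma*(f) = sigma(f) + j * 2*pi*f * eps0 * eps_r(f).

Dispersion is modelled with Cole-Cole relaxation terms

    eps_hat(omega) = eps_inf + sum_k delta_eps_k / (1 + (j omega tau_k)^(1-alpha_k))
                     + sigma_dc / (j omega eps0)

from which eps_r = Re(eps_hat without the DC pole) and
sigma = sigma_dc - omega*eps0*Im(relaxation sum).  A ``constant`` mode returns
the stored (sigma_dc, eps_inf) pair at every frequency; it is used for
engineered materials such as the electrode bulk.

The bundled parameter table (``data/tissues.yaml``) carries representative
literature-style values for the ten phantom materials; every value can be
overridden by loading a user table.  Skeletal muscle is treated as isotropic
with the longitudinal (along-fibre) conductivity.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .constants import EPS0

__all__ = [
    "ColeColeTerm",
    "DispersionModel",
    "ComplexConductivity",
    "MaterialSet",
    "evaluate",
    "complex_conductivity",
    "load_tissue_table",
    "default_materials",
]


@dataclass(frozen=True)
class ColeColeTerm:
    """One Cole-Cole relaxation: dispersion strength, time constant, broadening."""

    delta_eps: float  # dimensionless, >= 0
    tau: float  # seconds, > 0
    alpha: float = 0.0  # in [0, 1)

    def __post_init__(self) -> None:
        if self.delta_eps < 0:
            raise ValueError(f"delta_eps must be >= 0, got {self.delta_eps}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")


@dataclass(frozen=True)
class DispersionModel:
    """Dielectric model of one tissue.

    mode ``constant``: sigma_dc and eps_inf are returned at every frequency
    (relaxation terms are ignored).  mode ``cole_cole``: at least one term is
    required and sigma_dc is the DC conductivity exactly.
    """

    tissue_name: str
    mode: str  # "constant" | "cole_cole"
    sigma_dc: float  # S/m
    eps_inf: float  # dimensionless
    terms: tuple[ColeColeTerm, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "cole_cole"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sigma_dc <= 0:
            raise ValueError(
                f"{self.tissue_name}: sigma_dc must be > 0, got {self.sigma_dc}"
            )
        if self.eps_inf < 1:
            raise ValueError(
                f"{self.tissue_name}: eps_inf must be >= 1, got {self.eps_inf}"
            )
        if self.mode == "cole_cole" and len(self.terms) == 0:
            raise ValueError(f"{self.tissue_name}: cole_cole mode requires >= 1 term")


@dataclass(frozen=True)
class ComplexConductivity:
    """sigma* = sigma + j*omega*eps0*eps_r at one frequency."""

    sigma_star: complex  # S/m
    frequency: float  # Hz


def evaluate(model: DispersionModel, frequency: float) -> tuple[float, float]:
    """Return (sigma [S/m], eps_r) of ``model`` at ``frequency`` [Hz].

    DC is ``frequency == 0``; negative frequencies are a domain error.
    """
    if frequency < 0:
        raise ValueError(f"frequency must be >= 0, got {frequency}")
    if model.mode == "constant":
        return model.sigma_dc, model.eps_inf
    omega = 2.0 * math.pi * frequency
    relax = 0.0 + 0.0j
    for term in model.terms:
        relax += term.delta_eps / (1.0 + (1j * omega * term.tau) ** (1.0 - term.alpha))
    eps_r = model.eps_inf + relax.real
    sigma = model.sigma_dc - omega * EPS0 * relax.imag
    return sigma, eps_r


def complex_conductivity(model: DispersionModel, frequency: float) -> ComplexConductivity:
    """sigma*(f) = sigma(f) + j*2*pi*f*eps0*eps_r(f); purely real at DC."""
    sigma, eps_r = evaluate(model, frequency)
    omega = 2.0 * math.pi * frequency
    return ComplexConductivity(sigma + 1j * omega * EPS0 * eps_r, frequency)


def _model_from_record(rec: Mapping) -> DispersionModel:
    terms = tuple(
        ColeColeTerm(float(t["delta_eps"]), float(t["tau"]), float(t.get("alpha", 0.0)))
        for t in rec.get("terms", [])
    )
    return DispersionModel(
        tissue_name=str(rec["name"]),
        mode=str(rec["mode"]),
        sigma_dc=float(rec["sigma_dc"]),
        eps_inf=float(rec["eps_inf"]),
        terms=terms,
        note=str(rec.get("note", "")),
    )


def load_tissue_table(path: str | Path) -> dict[str, DispersionModel]:
    """Read a tissue table (YAML list of records) and validate each entry."""
    with open(path) as fh:
        records = yaml.safe_load(fh)
    if not isinstance(records, list):
        raise ValueError(f"{path}: expected a list of tissue records")
    models = {}
    for rec in records:
        model = _model_from_record(rec)
        if model.tissue_name in models:
            raise ValueError(f"duplicate tissue {model.tissue_name!r} in {path}")
        models[model.tissue_name] = model
    return models


def _bundled_table() -> dict[str, DispersionModel]:
    with resources.files("ccdosim.data").joinpath("tissues.yaml").open() as fh:
        records = yaml.safe_load(fh)
    return {r["name"]: _model_from_record(r) for r in records}


@dataclass(frozen=True)
class MaterialSet:
    """Tissue-name -> dispersion-model mapping with per-tissue conductivity scaling.

    ``sigma_scales`` multiplies sigma(f) of the named tissue (permittivity is
    unchanged); it backs the post-mortem blood-conductivity sweep.
    """

    models: Mapping[str, DispersionModel]
    sigma_scales: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "MaterialSet":
        return cls(models=_bundled_table())

    @classmethod
    def from_file(cls, path: str | Path) -> "MaterialSet":
        return cls(models=load_tissue_table(path))

    def with_overrides(self, overrides: Mapping[str, DispersionModel]) -> "MaterialSet":
        merged = dict(self.models)
        merged.update(overrides)
        return MaterialSet(models=merged, sigma_scales=dict(self.sigma_scales))

    def with_sigma_scale(self, tissue_name: str, factor: float) -> "MaterialSet":
        if tissue_name not in self.models:
            raise KeyError(f"unknown tissue {tissue_name!r}")
        if factor <= 0:
            raise ValueError(f"scale factor must be > 0, got {factor}")
        scales = dict(self.sigma_scales)
        scales[tissue_name] = factor
        return MaterialSet(models=self.models, sigma_scales=scales)

    def __contains__(self, tissue_name: str) -> bool:
        return tissue_name in self.models

    def evaluate(self, tissue_name: str, frequency: float) -> tuple[float, float]:
        model = self.models[tissue_name]
        sigma, eps_r = evaluate(model, frequency)
        return sigma * self.sigma_scales.get(tissue_name, 1.0), eps_r

    def complex_conductivity(self, tissue_name: str, frequency: float) -> ComplexConductivity:
        sigma, eps_r = self.evaluate(tissue_name, frequency)
        omega = 2.0 * math.pi * frequency
        return ComplexConductivity(sigma + 1j * omega * EPS0 * eps_r, frequency)

    def sigma_star_grid(self, phantom, frequency: float) -> np.ndarray:
        """Complex conductivity per voxel for every non-air label of ``phantom``.

        Air voxels get 0.  The skin-slice label (present only after a Total-BM
        electrode placement) takes its properties from
        ``phantom.slice_material``, not from the tissue table.
        """
        from .phantom import AIR, SKIN_SLICE  # local import: avoid cycle

        labels = phantom.labels
        present = np.unique(labels)
        lut = np.zeros(int(present.max()) + 1, dtype=complex)
        for lab in present:
            lab = int(lab)
            if lab == AIR:
                continue
            if lab == SKIN_SLICE:
                if phantom.slice_material is None:
                    raise ValueError(
                        "phantom contains skin-slice voxels but no slice material; "
                        "place Total-BM electrodes through place_electrode()"
                    )
                cc = complex_conductivity(phantom.slice_material, frequency)
                lut[lab] = cc.sigma_star
                continue
            name = phantom.tissue_map.get(lab)
            if name is None:
                raise KeyError(f"label {lab} missing from tissue_map")
            if name not in self.models:
                raise KeyError(f"no dispersion model for tissue {name!r} (label {lab})")
            lut[lab] = self.complex_conductivity(name, frequency).sigma_star
        return lut[labels]


def default_materials() -> MaterialSet:
    """The bundled ten-material table (override anything via MaterialSet methods)."""
    return MaterialSet.default()
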