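"""Nest-structured synthetic morphometric data generator.

Specimens are drawn per species: absolute cephalic size CS is normal
(truncated at zero by resampling) and every trait is a truncated-normal
ratio times CS, except CL and CWb which are reconstructed from CS and the
CL/CWb ratio so that CS = (CL + CWb)/2 holds exactly, and PoOC which is
scaled by CL.  A nest-level random effect contributes the fraction ``rho``
of each quantity's variance and is shared by nest mates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._reference_params import REFERENCE_CLASS_SIZES, REFERENCE_PARAMS
from .errors import ValidationError
from .io import MorphoTable, NEST_COLUMN

__all__ = [
    "SpeciesParams",
    "default_species_params",
    "reference_class_sizes",
    "simulate_dataset",
]


@dataclass
class SpeciesParams:
    """Per-species generator parameters.

    ``cs`` is (mean, sd, min, max) of absolute cephalic size in um;
    ``ratios`` maps ratio keys ("CL/CWb", "PoOC/CL", "<trait>/CS", or the
    absolute "Cdep") to (mean, sd, min, max) tuples.  ``rho`` is the
    nest-effect variance fraction.
    """

    name: str
    cs: tuple[float, float, float, float]
    ratios: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    rho: float = 0.3
    trait_correlation: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValidationError(f"{self.name}: rho must be in [0, 1)")
        if not 0.0 <= self.trait_correlation < 1.0:
            raise ValidationError(f"{self.name}: trait_correlation must be in [0, 1)")
        for key, (mean, sd, lo, hi) in {"CS": self.cs, **self.ratios}.items():
            if mean <= 0 or sd <= 0:
                raise ValidationError(f"{self.name}/{key}: mean and SD must be > 0")
            if not lo <= mean <= hi:
                raise ValidationError(
                    f"{self.name}/{key}: mean {mean} outside [{lo}, {hi}]")


def default_species_params(rho: float = 0.3) -> list[SpeciesParams]:
    """The eight frozen reference species parameter sets."""
    out = []
    for name, entries in REFERENCE_PARAMS.items():
        ratios = {k: v for k, v in entries.items() if k != "CS"}
        out.append(SpeciesParams(name, entries["CS"], ratios, rho))
    return out


def reference_class_sizes() -> dict[str, int]:
    """Published per-species specimen counts (confirmation-matrix rows)."""
    return dict(REFERENCE_CLASS_SIZES)


def _positive(mean: float, sd: float, structured: np.ndarray, resid_scale: float,
              rng: np.random.Generator) -> np.ndarray:
    """mean + sd * (structured + resid_scale * e), resampling e while <= 0."""
    n = len(structured)
    vals = mean + sd * (structured + resid_scale * rng.standard_normal(n))
    for _ in range(1000):
        bad = vals <= 0
        if not bad.any():
            return vals
        vals[bad] = mean + sd * (structured[bad]
                                 + resid_scale * rng.standard_normal(bad.sum()))
    raise ValidationError(f"cannot draw positive values for mean={mean}, sd={sd}")


def simulate_dataset(params: list[SpeciesParams], nests_per_species: int,
                     nest_size: int, rng: np.random.Generator | int | None = None,
                     *, sizes: dict[str, int] | None = None,
                     ) -> tuple[MorphoTable, pd.Series]:
    """Simulate a nest-structured specimen table plus true species labels.

    With ``sizes`` given (species -> total specimen count), nest sizes are
    as even as possible across ``nests_per_species`` nests instead of the
    fixed ``nest_size``.
    """
    if nests_per_species < 1 or nest_size < 1:
        raise ValidationError("nests_per_species and nest_size must be >= 1")
    if not params:
        raise ValidationError("no species parameters given")
    root = int(np.random.default_rng(rng).integers(2 ** 63))

    rows: list[dict] = []
    labels: list[str] = []
    spec_counter = 0
    for sp in params:
        # independent substream per species so reordering the parameter list
        # only permutes the output
        rng = np.random.default_rng([root, zlib.crc32(sp.name.encode())])
        if sizes is not None:
            total = sizes[sp.name]
            n_nests = min(nests_per_species, total)
            base, rem = divmod(total, n_nests)
            nest_sizes = [base + (1 if j < rem else 0) for j in range(n_nests)]
        else:
            nest_sizes = [nest_size] * nests_per_species
        sqrt_rho = np.sqrt(sp.rho)
        sqrt_comp = np.sqrt(1.0 - sp.rho)
        corr = sp.trait_correlation
        sq_c, sq_r = np.sqrt(corr), np.sqrt(1.0 - corr)
        for j, size in enumerate(nest_sizes):
            nest_id = f"{sp.name}-N{j + 1:03d}"
            # ratio deviations mix a factor shared across traits (strength
            # trait_correlation, mimicking allometric coupling) with per-trait
            # residuals; the same structure applies at the nest and the
            # individual level so within-nest whitening keeps nest centroids
            # isotropic.  Every marginal keeps the printed SD.
            g_nest = rng.standard_normal()
            g_spec = rng.standard_normal(size)
            u_cs = np.full(size, rng.standard_normal())
            draws = {"CS": _positive(sp.cs[0], sp.cs[1],
                                     sqrt_rho * u_cs, sqrt_comp, rng)}
            for key, (mean, sd, _lo, _hi) in sp.ratios.items():
                u_trait = rng.standard_normal()
                structured = (sqrt_rho * (sq_c * g_nest + sq_r * u_trait)
                              + sqrt_comp * sq_c * g_spec)
                draws[key] = _positive(mean, sd, structured,
                                       sqrt_comp * sq_r, rng)
            cs = draws["CS"]
            q = draws["CL/CWb"]
            cl = 2.0 * cs * q / (1.0 + q)
            cwb = 2.0 * cs / (1.0 + q)
            for i in range(size):
                spec_counter += 1
                row = {"specimen_id": f"SYN{spec_counter:05d}", NEST_COLUMN: nest_id,
                       "species": sp.name, "CL": cl[i], "CWb": cwb[i],
                       "CS": cs[i]}
                for key, vals in draws.items():
                    if key in ("CS", "CL/CWb"):
                        continue
                    trait, _, den = key.partition("/")
                    if den == "CS":
                        row[trait] = vals[i] * cs[i]
                    elif den == "CL":
                        row[trait] = vals[i] * cl[i]
                    elif den == "":
                        row[trait] = vals[i]          # absolute trait (Cdep)
                    else:  # pragma: no cover - unknown denominators rejected
                        raise ValidationError(f"unsupported ratio key {key!r}")
                rows.append(row)
                labels.append(sp.name)

    frame = pd.DataFrame(rows).set_index("specimen_id")
    trait_cols = [c for c in frame.columns if c not in (NEST_COLUMN, "species")]
    table = MorphoTable(frame, trait_cols)
    return table, pd.Series(labels, index=frame.index, name="species")
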