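"""Reusable constraint recipes reproducing the published fitting scenarios.

The jelly-candy relaxometry analysis is parsimony-driven: the Haribo
parameter table was obtained from a joint description of all jellies and
both temperatures in which the slow and fast dipolar constants and the
fast correlation time are common to every profile ("for all cases"), the
slow correlation time of bear/phantasia is common to both temperatures,
the offset A is common to both temperatures of each jelly, and only the
intermediate-dynamics parameters (plus the remaining per-profile slots)
vary freely.  The Vidal table was fitted per group, clamping the
parameters printed without uncertainties (C_s and C_f of the coke/fish/
pizza group and of roll jelly at the Haribo values).

These helpers translate that structure into :class:`ConstraintMap` /
fixed-value form so the scenario can be re-run on synthetic data.
"""

from __future__ import annotations

from .constraints import Constraint, ConstraintMap, free, shared
from .model import PARAM_NAMES
from .synthetic import ParameterCatalog, load_default_catalog

__all__ = ["haribo_rows", "haribo_constraint_map", "vidal_fixed_values"]


def haribo_rows(catalog: ParameterCatalog | None = None) -> list:
    """Haribo catalog rows in table order (4 jellies × 2 temperatures)."""
    catalog = catalog or load_default_catalog()
    return [row for row in catalog.rows if row.brand == "Haribo"]


def haribo_constraint_map(catalog: ParameterCatalog | None = None) -> ConstraintMap:
    """Joint-fit constraints for the 8 Haribo rows, in `haribo_rows` order.

    * ``c_s_dd`` and ``tau_f``: one global value each;
    * ``c_f_dd``: global, except free for balla-raspberry at 323 K (the
      only jelly whose fast dipolar constant moved with temperature);
    * ``tau_s``: one value across temperature for bear/phantasia, free
      per profile otherwise;
    * ``a``: one value per jelly across temperature;
    * ``c_i_dd``, ``tau_i``: free per profile (the intermediate dynamics
      carry the temperature dependence).
    """
    rows = haribo_rows(catalog)
    entries = []
    for row in rows:
        jelly = row.kinds[0]
        raspberry_323 = jelly == "balla-raspberry" and row.temperature_k == 323.0
        bear = jelly == "bear"
        entries.append({
            "c_s_dd": shared("cs_global"),
            "tau_f": shared("tauf_global"),
            "c_f_dd": free() if raspberry_323 else shared("cf_global"),
            "tau_s": shared("taus_bear") if bear else free(),
            "c_i_dd": free(),
            "tau_i": free(),
            "a": shared(f"a_{jelly}"),
        })
    return ConstraintMap(entries)


def vidal_fixed_values(row) -> dict:
    """Clamped parameters of a Vidal table row (printed without uncertainty)."""
    return {name: row.params[name].value for name in row.fixed_names()}
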