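"""Reference thermodynamic parameters for the cyanobacterial hsp17 RNA
thermometer and its stabilized variants.

These are the reported per-base-pair opening parameters determined by
imino-proton solvent-exchange NMR for the wild-type hairpin (``hsp17``) and
the bulge-closing mutant (``hsp17_rep``, mutation AAC(33-35)G whose new CG
pair is labelled ``G*``), together with the two-state CD unfolding
parameters of both constructs and of the terminus-stabilized ``hsp17_stab``.
They serve as inputs for construct comparisons, compensation analysis, and
as realistic ground truths for the synthetic-data generators.

Columns: dH_diss [kJ/mol], err_dH, dS_diss [J/(mol K)], err_dS,
dG20 [kJ/mol] (reported value at 20 degC), err_dG20.  Errors are Monte Carlo
errors.  Base pairs whose rates could not be measured over a sufficient
temperature range (terminal pairs, loop-flanking residues) are not listed.
"""

from __future__ import annotations

from .thermo_core import BasePairThermo

__all__ = [
    "HSP17_WT",
    "HSP17_REP",
    "HSP17_STEM2_MEMBERS",
    "HSP17_REP_EEC_MEMBERS",
    "MELTING_PARAMS",
    "EEC_REPORTED",
    "construct_table",
]

# label: (dH, err_dH, dS, err_dS, dG20, err_dG20)
_WT_ROWS = {
    "U4": (64.3, 8.5, 182.6, 30.9, 10.8, 0.6),
    "U38": (71.2, 10.8, 200.9, 39.3, 12.3, 0.7),
    "U37": (65.9, 12.8, 190.2, 46.9, 10.1, 1.0),
    "U11": (38.8, 3.7, 82.9, 13.1, 14.5, 0.2),
    "G30": (46.1, 3.7, 100.7, 12.9, 16.6, 0.2),
    "G28": (193.5, 23.7, 561.9, 77.5, 28.8, 1.0),
    "G27": (148.4, 20.4, 416.1, 67.1, 26.2, 0.8),
}

_REP_ROWS = {
    "U4": (53.0, 6.0, 137.8, 21.6, 12.6, 0.4),
    "U38": (102.1, 8.1, 283.0, 27.5, 19.2, 0.2),
    "U7/U37": (86.9, 8.0, 206.5, 26.2, 26.4, 0.4),
    "G*": (277.8, 19.2, 781.2, 59.3, 48.8, 1.9),
    "U32": (70.0, 4.3, 148.5, 14.1, 26.5, 0.3),
    "U31": (79.7, 12.6, 185.7, 42.7, 25.3, 0.3),
    "U11": (43.0, 3.6, 73.8, 12.2, 21.3, 0.2),
    "G30": (45.8, 4.6, 82.9, 15.3, 21.5, 0.2),
    "U12": (38.8, 7.5, 56.7, 25.7, 22.4, 0.2),
    "G28": (232.5, 14.4, 637.5, 44.4, 45.6, 1.4),
    "G27": (95.9, 4.2, 232.4, 13.7, 27.8, 0.3),
}


def _build(rows: dict) -> dict[str, BasePairThermo]:
    out = {}
    for label, (dh, edh, ds, eds, dg, edg) in rows.items():
        out[label] = BasePairThermo(
            label=label,
            dH_diss=dh,
            dS_diss=ds,
            err_dH=edh,
            err_dS=eds,
            dG20=dg,
            err_dG20=edg,
        )
    return out


#: Wild-type hsp17 per-base-pair opening thermodynamics.
HSP17_WT: dict[str, BasePairThermo] = _build(_WT_ROWS)

#: Stabilized hsp17_rep per-base-pair opening thermodynamics.
HSP17_REP: dict[str, BasePairThermo] = _build(_REP_ROWS)

#: Stem-II members entering the wild-type compensation fit.
HSP17_STEM2_MEMBERS = ("U11", "G30", "G28", "G27")

#: hsp17_rep compensation members: every measurable pair except the
#: terminus-proximal U4 and U38 (fraying outliers).
HSP17_REP_EEC_MEMBERS = (
    "U7/U37", "G*", "U32", "U31", "U11", "G30", "U12", "G28", "G27",
)

#: Two-state CD unfolding parameters: (dH_unf kJ/mol, dS_unf J/(mol K)).
MELTING_PARAMS = {
    "hsp17": (104.0, 326.0),
    "hsp17_rep": (431.0, 1278.0),
    "hsp17_stab": (282.0, 870.0),
}

#: Reported compensation temperatures/offsets: (Tc degC, sd, y0 kJ/mol, sd).
EEC_REPORTED = {
    "hsp17": (49.4, 2.7, 13.0, 1.0),
    "hsp17_rep": (61.6, 2.3, 18.9, 0.8),
}


def construct_table(name: str) -> dict[str, BasePairThermo]:
    """Return the per-base-pair table for ``"hsp17"`` or ``"hsp17_rep"``."""
    if name == "hsp17":
        return dict(HSP17_WT)
    if name == "hsp17_rep":
        return dict(HSP17_REP)
    raise KeyError(f"unknown construct {name!r}")
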