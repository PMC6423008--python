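"""Published parameter sets for bile-salt binding to human I-BABP.

These are the fitted experimental values reported for glycocholic acid
(GCA) and glycochenodeoxycholic acid (GCDA) binding, used throughout the
package as ground truths for synthetic-data recovery studies and as
worked-example inputs.  Raw instrument data are not deposited, so these
numbers are inputs, not outputs, of this package.
"""

from __future__ import annotations

from .itc import BindingParams
from .stoppedflow import KineticScheme

__all__ = [
    "BINDING_PARAMS",
    "HILL_COEFFICIENTS",
    "ENTROPIES_TDS",
    "KINETIC_SCHEMES",
    "EXCHANGE_GLOBAL",
    "EXCHANGE_INDIVIDUAL_PH54",
    "PKA_APO",
    "PKA_HOLO",
    "FIG3_LIGAND_UM",
]

# ITC stepwise thermodynamics at 25 C (Kd in M, dH in kcal/mol)
BINDING_PARAMS = {
    ("GCA", 5.8): BindingParams(kd1=105e-6, kd2=2.4e-6, dh1=-1.3, dh2=-9.3),
    ("GCA", 7.2): BindingParams(kd1=276e-6, kd2=4.3e-6, dh1=-0.3, dh2=-10.0),
    ("GCDA", 5.8): BindingParams(kd1=47e-6, kd2=13.2e-6, dh1=0.86, dh2=-9.9),
    ("GCDA", 7.2): BindingParams(kd1=76e-6, kd2=21e-6, dh1=2.0, dh2=-12.1),
}

# printed Hill coefficients and stepwise entropies (TdS1, TdS2, kcal/mol)
HILL_COEFFICIENTS = {
    ("GCA", 5.8): 1.74,
    ("GCA", 7.2): 1.78,
    ("GCDA", 5.8): 1.31,
    ("GCDA", 7.2): 1.31,
}
ENTROPIES_TDS = {
    ("GCA", 5.8): (4.1, -1.6),
    ("GCA", 7.2): (4.6, -2.7),
    ("GCDA", 5.8): (6.76, -3.24),
    ("GCDA", 7.2): (7.62, -5.72),
}

# four-step kinetic schemes at 15 C (first-order s^-1, second-order s^-1 uM^-1)
KINETIC_SCHEMES = {
    ("GCA", 5.8): KineticScheme(k1=1900, k_1=200, k2=0.28, k_2=64, k3=1.1, k_3=2.2, k4=1.1, k_4=7.4),
    ("GCA", 7.2): KineticScheme(k1=1400, k_1=170, k2=0.14, k_2=28, k3=6.4, k_3=38, k4=0.8, k_4=7.0),
    ("GCDA", 5.8): KineticScheme(k1=1900, k_1=200, k2=1.48, k_2=73, k3=2.8, k_3=50, k4=0.2, k_4=14.9),
    ("GCDA", 7.2): KineticScheme(k1=1400, k_1=170, k2=1.22, k_2=164, k3=2.2, k_3=24, k4=1.4, k_4=16.5),
}

#: ligand concentrations (uM) of the kinetic series; traces were recorded
#: up to a final bile-salt concentration of 500 uM
FIG3_LIGAND_UM = (20.0, 30.0, 40.0, 50.0, 100.0, 150.0, 300.0, 500.0)

# global two-state exchange fits of the ligand-free protein, 10 C:
# (kex s^-1, p_E fraction) per condition/cluster
EXCHANGE_GLOBAL = {
    ("6.3", "cluster_I"): (836.0, 0.031),
    ("6.3", "cluster_II"): (294.0, 0.018),
    ("6.8", "merged"): (1467.0, 0.044),
    ("8.0", "merged"): (1453.0, 0.057),
}

# individual fits at pH 5.4: residue -> (kex s^-1, p_E fraction)
EXCHANGE_INDIVIDUAL_PH54 = {
    "T3": (54.0, 0.08),
    "T73": (10.0, 0.19),
    "G76": (1170.0, 0.21),
    "V91": (1852.0, 0.24),
    "Y97": (1057.0, 0.003),
    "T100": (479.0, 0.007),
    "S101": (651.0, 0.23),
    "E110": (480.0, 0.004),
}

# apparent histidine pKa values (15N titrations, 10 C)
PKA_APO = {"H52": 6.7, "H57": 6.4, "H98": 6.6}
PKA_HOLO = {"H52": 6.6, "H57": 7.9, "H98": 7.0}
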