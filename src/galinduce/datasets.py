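"""Published phenotype values for the GAL1 induction strains.

These are the printed strain phenotypes (times in minutes, steady-state
expression as a GAL1/ACT1 ratio) for wild-type H2A.Z (*HTZ1*), the deletion
(*htz1*Δ), the unacetylatable allele (*htz1-K3,8,10,14R*), and a second
wild-type/deletion pair from an independent strain background
(CRY1 / DBY50).  "Primary" is induction after long-term glucose repression;
"secondary" is reinduction after a short (12 h) glucose interlude, where the
fitted onset times were indistinguishable from zero.

They serve as inputs for the comparison-table operations and as anchors for
the synthetic-data presets; they are data, not results of this package.
"""

from __future__ import annotations

from .phenotypes import PhenotypeRow

__all__ = ["PUBLISHED_PHENOTYPES", "published_rows", "STRAIN_GROUPS"]

# strain -> condition -> (activation_time, steady_state_level, time_to_half,
#                         activation_to_half); minutes / expression ratio
PUBLISHED_PHENOTYPES: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "HTZ1": {
        "primary": (204.8, 0.9, 234.3, 29.5),
        "secondary": (0.0, 0.9, 14.8, 14.8),
    },
    "htz1D": {
        "primary": (214.1, 0.7, 362.4, 148.3),
        "secondary": (0.0, 0.6, 38.9, 38.9),
    },
    "htz1-K3,8,10,14R": {
        "primary": (191.3, 0.8, 375.4, 184.2),
        "secondary": (0.0, 0.7, 29.7, 29.7),
    },
    "HTZ1 (CRY1)": {
        "primary": (204.4, 0.8, 243.7, 39.3),
        "secondary": (0.0, 1.0, 28.4, 28.4),
    },
    "htz1D (DBY50)": {
        "primary": (218.9, 0.7, 356.3, 137.4),
        "secondary": (0.0, 0.7, 110.4, 110.4),
    },
}

#: Strains compared against each reference (two independent backgrounds).
STRAIN_GROUPS: dict[str, tuple[str, ...]] = {
    "HTZ1": ("HTZ1", "htz1D", "htz1-K3,8,10,14R"),
    "HTZ1 (CRY1)": ("HTZ1 (CRY1)", "htz1D (DBY50)"),
}


def published_rows(strains=None, conditions=("primary", "secondary")) -> list[PhenotypeRow]:
    """The published phenotypes as PhenotypeRow objects."""
    rows = []
    for strain, by_cond in PUBLISHED_PHENOTYPES.items():
        if strains is not None and strain not in strains:
            continue
        for cond in conditions:
            act, ss, half, act_to_half = by_cond[cond]
            rows.append(
                PhenotypeRow(
                    strain=strain,
                    condition=cond,
                    activation_time=act,
                    steady_state_level=ss,
                    time_to_half=half,
                    activation_to_half=act_to_half,
                )
            )
    return rows
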