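"""Published group means bundled as reference fixtures.

These are the printed group summaries (mean, SEM, n = 9 per temperature) for
wild Nassau grouper (*Epinephelus striatus*) swum to Ucrit at 22 and 30 degC,
plus the cross-species comparison rows and the printed Q10 table.  They are
inputs for derived-quantity checks and the species comparison — the pipeline
never reads its own results from here.

Note on the printed Q10 values: they are not exactly reproducible from the
group means via (R2/R1)**(10/(T2-T1)) (e.g. resting fH gives 2.01 against a
printed 2.06); they are bundled for reference only and are not a validation
surface.  Similarly the cross-species row for this study prints FAS 3.50
while the group table's FAS (MMR/SMR) is 3.63.
"""
from __future__ import annotations

from dataclasses import dataclass

N_PER_GROUP = 9

#: parameter -> {temp_c: (mean, sem)}
TABLE1: dict[str, dict[int, tuple[float, float]]] = {
    "ucrit":     {22: (0.70, 0.04),   30: (0.96, 0.04)},
    "smr":       {22: (44.08, 4.09),  30: (117.71, 12.57)},
    "rmr":       {22: (53.73, 3.99),  30: (129.68, 12.93)},
    "mmr":       {22: (230.32, 24.25), 30: (409.40, 26.99)},
    "aas":       {22: (186.23, 23.92), 30: (291.69, 22.30)},
    "fas":       {22: (5.49, 0.69),   30: (3.63, 0.26)},
    "aas_r":     {22: (176.59, 23.32), 30: (279.72, 19.97)},
    "fas_r":     {22: (4.38, 0.48),   30: (3.27, 0.19)},
    "fh_rest":   {22: (33.3, 0.8),    30: (58.3, 4.2)},
    "fh_max":    {22: (62.4, 2.3),    30: (118.8, 3.4)},
    "fh_scope":  {22: (29.1, 1.9),    30: (60.5, 3.9)},
    "fh_fscope": {22: (1.87, 0.06),   30: (2.10, 0.14)},
    "vs_rest":   {22: (0.425, 0.032), 30: (0.385, 0.031)},
    "vs_max":    {22: (0.589, 0.039), 30: (0.462, 0.023)},
    "vs_scope":  {22: (0.164, 0.021), 30: (0.078, 0.015)},
    "vs_fscope": {22: (1.40, 0.06),   30: (1.24, 0.06)},
    "q_rest":    {22: (14.14, 1.21),  30: (23.10, 2.73)},
    "q_max":     {22: (35.84, 2.62),  30: (51.16, 3.36)},
    "q_scope":   {22: (21.71, 1.83),  30: (28.07, 2.00)},
    "q_fscope":  {22: (2.58, 0.15),   30: (2.35, 0.18)},
    "ext_rest":  {22: (0.064, 0.005), 30: (0.098, 0.010)},
    "ext_max":   {22: (0.107, 0.006), 30: (0.149, 0.011)},
    "ext_scope": {22: (0.043, 0.008), 30: (0.052, 0.007)},
    "ext_fscope": {22: (1.76, 0.18),  30: (1.59, 0.10)},
}

#: printed Q10 values (22 -> 30 degC); reference only, see module docstring
TABLE2_Q10: dict[str, float] = {
    "smr": 4.07, "rmr": 3.42, "mmr": 2.50, "aas": 2.49, "ucrit": 1.52,
    "fh_rest": 2.06, "fh_max": 2.29, "fh_scope": 2.62,
    "vs_rest": 0.85, "vs_max": 0.75, "vs_scope": 0.78,
    "q_rest": 1.87, "q_max": 1.60, "q_scope": 1.52,
    "ext_rest": 1.89, "ext_max": 1.57, "ext_scope": 1.04,
}

#: parameter -> {temp_c: {"rest": (mean, sem), "recovery_2h": (mean, sem)}}
TABLE3: dict[str, dict[int, dict[str, tuple[float, float]]]] = {
    "mo2": {22: {"rest": (53.73, 3.99), "recovery_2h": (56.93, 7.83)},
            30: {"rest": (129.68, 12.93), "recovery_2h": (179.55, 16.33)}},
    "fh":  {22: {"rest": (33.3, 0.8), "recovery_2h": (34.2, 2.1)},
            30: {"rest": (58.3, 4.2), "recovery_2h": (72.4, 7.4)}},
    "vs":  {22: {"rest": (0.425, 0.032), "recovery_2h": (0.482, 0.029)},
            30: {"rest": (0.385, 0.031), "recovery_2h": (0.374, 0.024)}},
    "q":   {22: {"rest": (14.14, 1.21), "recovery_2h": (13.67, 3.37)},
            30: {"rest": (23.10, 2.73), "recovery_2h": (27.00, 3.17)}},
    "ext": {22: {"rest": (0.064, 0.005), "recovery_2h": (0.050, 0.004)},
            30: {"rest": (0.098, 0.010), "recovery_2h": (0.103, 0.013)}},
}


@dataclass(frozen=True)
class SpeciesComparison:
    """One row of the cross-species comparison (rates at >= 25 degC)."""

    species: str
    temp_c: float
    mass_g: str
    smr: float
    mmr: float
    aas: float
    fas: float
    ucrit: float | None
    lifestyle: str


TABLE4: tuple[SpeciesComparison, ...] = (
    SpeciesComparison("Yellowfin tuna (Thunnus albacares)", 25, "2200",
                      253.0, 2530.0, 2277.0, 10.00, 2.1,
                      "Pelagic high performer/active forager"),
    SpeciesComparison("Mahi-mahi (Coryphaena hippurus)", 28, "30-40",
                      452.5, 1685.8, 1122.4, 3.73, 5.46,
                      "Pelagic/deep open ocean top predator"),
    SpeciesComparison("Cobia (Rachycentron canadum)", 26, "300-400",
                      152.3, 1017.0, 864.8, 6.68, 2.01,
                      "Pelagic/coastal opportunistic predator"),
    SpeciesComparison("Schoolmaster snapper (Lutjanus apodus)", 29, "300",
                      169.2, 737.7, 568.5, 4.41, 2.42,
                      "Mangrove/reef opportunistic predator"),
    SpeciesComparison("Australasian snapper (Chrysophrys auratus)", 25, "115",
                      175.3, 579.0, 403.7, 3.30, None,
                      "Benthopelagic, opportunistic predator"),
    SpeciesComparison("Gag grouper (Mycteroperca microlepis)", 30, "1800-1950",
                      95.6, 430.0, 334.4, 4.50, 1.48,
                      "Benthic reef ambush predator"),
    SpeciesComparison("Nassau grouper (Epinephelus striatus), prior study", 30,
                      "750-800", 62.8, 453.3, 390.5, 7.22, 2.0,
                      "Benthic reef ambush predator"),
    SpeciesComparison("Nassau grouper (Epinephelus striatus), this study", 30,
                      "800-1000", 117.7, 409.4, 291.7, 3.50, 0.96,
                      "Benthic reef ambush predator"),
)

THIS_STUDY_ROW = TABLE4[-1]
SCHOOLMASTER_SNAPPER_ROW = TABLE4[3]
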