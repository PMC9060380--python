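"""Physical constants for Sr-isotope otolith chronologies.

Natural isotopic abundances and atomic masses are IUPAC values; the global
marine value (GMV) and the habitat voltage thresholds are the conventional
anchors used when reading ⁸⁷Sr/⁸⁶Sr transects of diadromous fishes.
"""

from __future__ import annotations

# Ocean-water 87Sr/86Sr, constant on millennial timescales.
GMV = 0.70918
#: 2-SD band around the GMV within which a ratio is "marine".
GMV_TOL = 0.00006

#: Community consensus 87Sr/86Sr of the NIST SRM 987 SrCO3 standard.
SRM987_RATIO = 0.710248

#: Sr concentration of the FEBs-1 otolith reference material, mg/kg.
FEBS1_SR_MGKG = 2055.0

#: Habitat thresholds on the (corrected) 88Sr beam, volts.
FW_THRESHOLD_V = 6.13     # below: freshwater (~850 mg/kg Sr)
MARINE_THRESHOLD_V = 12.26  # above: marine (~1700 mg/kg Sr)

#: Seawater Sr concentration, mg/L.
SEAWATER_SR_MGL = 7.9

#: Laser scan speed (µm/s) and spot diameter (µm) of the ablation runs.
SCAN_SPEED_UM_S = 5.0
SPOT_UM = 35.0

#: Length of the gas-blank (laser warm-up) window used for blank means, s.
BLANK_WINDOW_S = 30.0

# --- isotopic abundances (atom fractions) -------------------------------

SR_ABUNDANCE = {84: 0.0056, 86: 0.0986, 87: 0.0700, 88: 0.8258}
RB_ABUNDANCE = {85: 0.7217, 87: 0.2783}
#: Natural 87Rb/85Rb atom ratio used for peak stripping.
RB_87_85 = RB_ABUNDANCE[87] / RB_ABUNDANCE[85]

CA_ABUNDANCE = {40: 0.96941, 42: 0.00647, 43: 0.00135,
                44: 0.02086, 46: 0.00004, 48: 0.00187}
AR_ABUNDANCE = {36: 0.003336, 38: 0.000629, 40: 0.996035}

#: Atomic masses (u) of the dominant species at each nominal m/z channel:
#: Sr at 84, 86, 87, 88 and Rb at 85.
ATOMIC_MASS = {
    84: 83.913419,
    85: 84.911790,   # 85Rb
    86: 85.9093,     # 86Sr
    87: 86.9089,     # 87Sr
    88: 87.905612,
}
#: Mass of 87Rb (u), used when stripping the Rb isobar off m/z 87.
MASS_RB87 = 86.909180

#: Detector channels recorded in a run.
CHANNELS = (82, 83, 84, 85, 86, 87, 88)


def _dimer_distribution() -> dict[int, float]:
    """Ca–Ca dimer isotopologue probabilities by nominal m/z (80–96)."""
    isotopes = sorted(CA_ABUNDANCE)
    dist: dict[int, float] = {}
    for i, a in enumerate(isotopes):
        for b in isotopes[i:]:
            p = CA_ABUNDANCE[a] * CA_ABUNDANCE[b]
            if a != b:
                p *= 2.0
            dist[a + b] = dist.get(a + b, 0.0) + p
    return dist


def _argide_distribution() -> dict[int, float]:
    """Ca–Ar argide isotopologue probabilities by nominal m/z (76–88)."""
    dist: dict[int, float] = {}
    for ca, pca in CA_ABUNDANCE.items():
        for ar, par in AR_ABUNDANCE.items():
            dist[ca + ar] = dist.get(ca + ar, 0.0) + pca * par
    return dist


#: Full isotopologue distributions (sum to 1 over all masses).
CA_DIMER_DIST = _dimer_distribution()
CA_ARGIDE_DIST = _argide_distribution()
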