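"""The TCR/CD28 signal-initiation model: network content, knockdowns, readouts.

The model covers the first 60 s of signaling in a single T cell stimulated
with a pre-crosslinked anti-CD3/anti-CD28 antibody ligand.  Mechanistic
content, in brief:

* **Stimulus** — a crosslinker species with anti-CD3E, anti-CD3G and
  anti-CD28 arms, injected at t=0 after equilibration.
* **Constitutive CD28-LCK recruitment** — LCK docked on ligand-engaged CD28
  phosphorylates CD3G Y171 without requiring prior receptor phosphorylation
  (the receptor-independent "class 1" route) and trans-autophosphorylates
  LCK Y394 (the activating site).
* **ITAM cascade ("class 2")** — active LCK (Y394~P, Y505~U) phosphorylates
  CD3E Y188; ZAP70 is recruited by its SH2 domain to phospho-Y188 and is then
  phosphorylated by LCK at Y493 (and Y292); active ZAP70 phosphorylates the
  adaptors LAT and LCP2; LAT recruits GRAP2, GRAP2 recruits LCP2, and
  phospho-LCP2 recruits NCK1 and (via Y145) PLCG1, which is then
  phosphorylated at Y771/Y783.
* **Shortcut to WAS** — the NCK1 N-terminal SH3 domain binds the CD3E
  proline-rich sequence while Y188 is unphosphorylated (SH3-PRS binding and
  ITAM phosphorylation are mutually exclusive), the NCK1 C-terminal SH3
  domain binds WAS, and membrane-anchored WAS is phosphorylated at Y291 by
  active LCK — before any ITAM-dependent signaling has engaged.  ITAM
  phosphorylation disengages the shortcut as the LCP2-dependent long route
  takes over.
* **Negative regulation** — PAG1 Y163 (phosphorylated by open LCK) recruits
  CSK, which phosphorylates the inhibitory LCK C-terminal Y505; DOK1 Y449
  binds CSK and DOK2 Y299 binds RASA1; LCK Y192 (in the SH2 domain) carries
  basal phosphorylation.
* **PTPN6 positive feedback** — LCK phosphorylates PTPN6 Y566 (activating);
  active PTPN6 dephosphorylates the negative-regulatory sites LCK Y192,
  PAG1 Y163, DOK1 Y449 and DOK2 Y299.  Stripping PAG1 Y163 releases CSK and
  lets constitutive phosphatase activity clear LCK Y505, further activating
  LCK — the loops that make the phosphatase a positive regulator early on.

Knockdowns are modeled by setting a protein's seed copy number to zero.

The shipped rate constants and copy numbers are reconstructed defaults (the
original fitted table is not reproducible here); copy numbers are scaled to
~100 per species so that multi-run Monte Carlo averaging over several
genotypes stays cheap.  The directional claims the model is used for are
insensitive to this scale.
"""

from __future__ import annotations

import importlib.resources as _resources
from dataclasses import dataclass, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .rule_model import ModelSpec, parse_model, validate_model
from .nf_sim import SimProtocol, average_runs, mean_course, simulate_runs

__all__ = [
    "SiteRoster",
    "RosterEntry",
    "Perturbation",
    "RelativeTimeCourse",
    "MEASURED_PROTEINS",
    "ADDITIONAL_PROTEINS",
    "load_roster",
    "load_default_parameters",
    "build_tcr_model",
    "default_protocol",
    "apply_knockdown",
    "relative_timecourse",
    "cumulative_auc",
    "scale_to_endpoint",
    "half_rise_time",
    "site_class_of",
    "simulate_sites",
]

#: Proteins carrying the 16 measured pTyr sites.
MEASURED_PROTEINS = (
    "LCK", "ZAP70", "LAT", "LCP2", "PLCG1", "WAS", "PTPN6", "PAG1", "DOK1", "DOK2",
)

#: Proteins included because they regulate the measured sites (the stimulus
#: crosslinker species is not counted as a protein of the network).
ADDITIONAL_PROTEINS = ("CD3E", "CD3G", "CD28", "NCK1", "GRAP2", "CSK", "RASA1")


@dataclass(frozen=True)
class RosterEntry:
    protein: str
    residue: int
    observable: str  # model observable counting the phosphorylated site
    site_class: int  # 1 | 2 | 3
    measured: bool


@dataclass(frozen=True)
class SiteRoster:
    entries: tuple[RosterEntry, ...]

    def __post_init__(self):
        measured = [e for e in self.entries if e.measured]
        if len(measured) != 16:
            raise ValueError(f"roster must flag exactly 16 measured sites, got {len(measured)}")
        if len({e.protein for e in measured}) != 10:
            raise ValueError("measured sites must span exactly 10 proteins")
        if any(e.site_class not in (1, 2, 3) for e in self.entries):
            raise ValueError("site classes must be 1, 2 or 3")

    def get(self, protein: str, residue: int) -> RosterEntry:
        for e in self.entries:
            if e.protein == protein and e.residue == residue:
                return e
        raise KeyError(f"site ({protein}, {residue}) not in roster")

    def measured(self) -> tuple[RosterEntry, ...]:
        return tuple(e for e in self.entries if e.measured)


@dataclass(frozen=True)
class Perturbation:
    """An in-silico knockdown: the protein's copy number is set to zero."""

    protein: str
    kind: str = "knockdown"


@dataclass(frozen=True)
class RelativeTimeCourse:
    """Phosphorylation relative to the unstimulated (t=0) baseline."""

    site: str
    times: np.ndarray
    values: np.ndarray
    log2: bool = False

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise ValueError("times/values length mismatch")


# ---------------------------------------------------------------------------
# shipped data files


def _read_data_text(name: str) -> str:
    return (_resources.files("tcr_phosdyn") / "data" / name).read_text()


def load_roster() -> SiteRoster:
    """The shipped site roster (reconstructed; 16 measured sites, 10 proteins)."""
    df = pd.read_csv(_io_from(_read_data_text("site_roster.tsv")), sep="\t", comment="#")
    entries = tuple(
        RosterEntry(
            protein=r.protein,
            residue=int(r.residue),
            observable=r.observable,
            site_class=int(r.site_class),
            measured=bool(r.measured),
        )
        for r in df.itertuples()
    )
    return SiteRoster(entries=entries)


def load_default_parameters() -> dict[str, float]:
    """The shipped reconstructed parameter table (name -> value)."""
    df = pd.read_csv(_io_from(_read_data_text("default_parameters.tsv")), sep="\t", comment="#")
    return {str(r.name): float(r.value) for r in df.itertuples()}


def _io_from(text: str):
    import io

    return io.StringIO(text)


# ---------------------------------------------------------------------------
# model construction


def _site_observables(roster: SiteRoster) -> list[str]:
    comp_of = {
        ("LCK", 192): "LCK(y192~P!?)",
        ("LCK", 394): "LCK(y394~P!?)",
        ("LCK", 505): "LCK(y505~P!?)",
        ("ZAP70", 292): "ZAP70(y292~P!?)",
        ("ZAP70", 493): "ZAP70(y493~P!?)",
        ("LAT", 191): "LAT(y191~P!?)",
        ("LAT", 226): "LAT(y226~P!?)",
        ("LCP2", 128): "LCP2(y128~P!?)",
        ("LCP2", 145): "LCP2(y145~P!?)",
        ("PLCG1", 771): "PLCG1(y771~P!?)",
        ("PLCG1", 783): "PLCG1(y783~P!?)",
        ("WAS", 291): "WAS(y291~P!?)",
        ("PTPN6", 566): "PTPN6(y566~P!?)",
        ("PAG1", 163): "PAG1(y163~P!?)",
        ("DOK1", 449): "DOK1(y449~P!?)",
        ("DOK2", 299): "DOK2(y299~P!?)",
        ("CD3G", 171): "CD3G(y171~P!?)",
        ("CD3E", 188): "CD3E(y188~P!?)",
    }
    lines = []
    for e in roster.entries:
        lines.append(f"  Molecules {e.observable} {comp_of[(e.protein, e.residue)]}")
    return lines


def build_tcr_model(
    param_table: Optional[Mapping[str, float]] = None,
    *,
    shortcut_enabled: bool = True,
    ptpn6_feedback_enabled: bool = True,
    ptpn6_direct_y505: bool = False,
    roster: Optional[SiteRoster] = None,
) -> ModelSpec:
    """Assemble the TCR/CD28 model as a validated :class:`ModelSpec`.

    ``shortcut_enabled`` toggles the NCK1 N-SH3 / CD3E PRS binding rules (the
    shortcut route to WAS); ``ptpn6_feedback_enabled`` toggles the
    dephosphorylation actions of active PTPN6; ``ptpn6_direct_y505`` adds a
    direct PTPN6 action on LCK Y505 (off by default — the model's narrative
    route to Y505 runs indirectly through PAG1 dephosphorylation).
    """
    params = dict(load_default_parameters())
    if param_table:
        unknown = set(param_table) - set(params)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        params.update(param_table)
    roster = roster or load_roster()

    p_lines = [f"  {k} {v:.12g}" for k, v in sorted(params.items())]

    mt_lines = [
        "  Ligand(cd3e,cd3g,cd28)  # loc=E",
        "  CD28(lig,lck)  # loc=M",
        "  CD3E(lig,prs,y188~U~P)  # loc=M",
        "  CD3G(lig,y171~U~P)  # loc=M",
        "  LCK(cd28,y192~U~P,y394~U~P,y505~U~P)  # loc=M",
        "  ZAP70(sh2,y292~U~P,y493~U~P)",
        "  LAT(y191~U~P,y226~U~P)  # loc=M",
        "  GRAP2(sh2,sh3)",
        "  LCP2(grap2,y128~U~P,y145~U~P)",
        "  NCK1(nsh3,sh2,csh3)",
        "  WAS(prs,y291~U~P)",
        "  PLCG1(sh2,y771~U~P,y783~U~P)",
        "  PTPN6(y566~U~P)",
        "  PAG1(y163~U~P)  # loc=M",
        "  CSK(sh2)",
        "  DOK1(y449~U~P)",
        "  DOK2(y299~U~P)",
        "  RASA1(sh2)",
    ]

    seed_lines = [
        "  CD28(lig,lck) N_CD28",
        "  CD3E(lig,prs,y188~U) N_CD3E",
        "  CD3G(lig,y171~U) N_CD3G",
        "  LCK(cd28,y192~U,y394~U,y505~U) N_LCK",
        "  ZAP70(sh2,y292~U,y493~U) N_ZAP70",
        "  LAT(y191~U,y226~U) N_LAT",
        "  GRAP2(sh2,sh3) N_GRAP2",
        "  LCP2(grap2,y128~U,y145~U) N_LCP2",
        "  NCK1(nsh3,sh2,csh3) N_NCK1",
        "  WAS(prs,y291~U) N_WAS",
        "  PLCG1(sh2,y771~U,y783~U) N_PLCG1",
        "  PTPN6(y566~U) N_PTPN6",
        "  PAG1(y163~U) N_PAG1",
        "  CSK(sh2) N_CSK",
        "  DOK1(y449~U) N_DOK1",
        "  DOK2(y299~U) N_DOK2",
        "  RASA1(sh2) N_RASA1",
    ]
    # seed copy numbers are parameter references; resolve them to integers here
    resolved_seed_lines = []
    for line in seed_lines:
        mol, sym = line.rsplit(None, 1)
        resolved_seed_lines.append(f"{mol} {int(round(params[sym]))}")

    rules: list[str] = [
        # stimulus engagement (crosslinked antibody arms; effectively irreversible
        # on the 60 s window)
        "  lig_cd3e: Ligand(cd3e) + CD3E(lig) -> Ligand(cd3e!1).CD3E(lig!1) k_lig_on",
        "  lig_cd3g: Ligand(cd3g) + CD3G(lig) -> Ligand(cd3g!1).CD3G(lig!1) k_lig_on",
        "  lig_cd28: Ligand(cd28) + CD28(lig) -> Ligand(cd28!1).CD28(lig!1) k_lig_on",
        # constitutive CD28-LCK recruitment
        "  lck_cd28_bind: LCK(cd28) + CD28(lck) -> LCK(cd28!1).CD28(lck!1) k_lckcd28_on",
        "  lck_cd28_unbind: LCK(cd28!1).CD28(lck!1) -> LCK(cd28) + CD28(lck) k_lckcd28_off",
        # constitutive NCK1 C-SH3 / WAS PRS interaction
        "  nck_was_bind: NCK1(csh3) + WAS(prs) -> NCK1(csh3!1).WAS(prs!1) k_nckwas_on",
        "  nck_was_unbind: NCK1(csh3!1).WAS(prs!1) -> NCK1(csh3) + WAS(prs) k_nckwas_off",
        # LCK activation: trans-autophosphorylation of Y394 on receptor-engaged LCK
        "  lck_y394_trans: LCK(y505~U) + LCK(y394~U,cd28!1).CD28(lck!1,lig!+) -> "
        "LCK(y505~U) + LCK(y394~P,cd28!1).CD28(lck!1,lig!+) k_y394",
        "  lck_y394_dephos: LCK(y394~P) -> LCK(y394~U) k_y394_off",
        # receptor (ITAM) phosphorylation; CD3E Y188 requires a free PRS
        "  cd3e_y188_phos: LCK(y394~P,y505~U) + CD3E(lig!+,prs,y188~U) -> "
        "LCK(y394~P,y505~U) + CD3E(lig!+,prs,y188~P) k_itam",
        "  cd3e_y188_dephos: CD3E(y188~P) -> CD3E(y188~U) k_site_off",
        # class-1 route: LCK docked on ligand-engaged CD28 phosphorylates CD3G Y171
        "  cd3g_y171_phos: LCK(y505~U,cd28!1).CD28(lck!1,lig!+) + CD3G(lig!+,y171~U) -> "
        "LCK(y505~U,cd28!1).CD28(lck!1,lig!+) + CD3G(lig!+,y171~P) k_y171",
        "  cd3g_y171_dephos: CD3G(y171~P) -> CD3G(y171~U) k_site_off",
        # ZAP70 recruitment to phospho-ITAM and activation-loop phosphorylation
        "  zap_bind: ZAP70(sh2) + CD3E(y188~P) -> ZAP70(sh2!1).CD3E(y188~P!1) k_zap_on",
        "  zap_unbind: ZAP70(sh2!1).CD3E(y188~P!1) -> ZAP70(sh2) + CD3E(y188~P) k_zap_off",
        "  zap_y493_phos: LCK(y394~P,y505~U) + ZAP70(sh2!+,y493~U) -> "
        "LCK(y394~P,y505~U) + ZAP70(sh2!+,y493~P) k_y493",
        "  zap_y493_dephos: ZAP70(y493~P) -> ZAP70(y493~U) k_site_off",
        "  zap_y292_phos: LCK(y394~P,y505~U) + ZAP70(sh2!+,y292~U) -> "
        "LCK(y394~P,y505~U) + ZAP70(sh2!+,y292~P) k_y292",
        "  zap_y292_dephos: ZAP70(y292~P) -> ZAP70(y292~U) k_site_off",
        # ZAP70 substrates: LAT and LCP2
        "  lat_y191_phos: ZAP70(y493~P) + LAT(y191~U) -> ZAP70(y493~P) + LAT(y191~P) k_lat",
        "  lat_y191_dephos: LAT(y191~P) -> LAT(y191~U) k_site_off",
        "  lat_y226_phos: ZAP70(y493~P) + LAT(y226~U) -> ZAP70(y493~P) + LAT(y226~P) k_lat2",
        "  lat_y226_dephos: LAT(y226~P) -> LAT(y226~U) k_site_off",
        "  lcp2_y128_phos: ZAP70(y493~P) + LCP2(y128~U) -> ZAP70(y493~P) + LCP2(y128~P) k_lcp2",
        "  lcp2_y128_dephos: LCP2(y128~P) -> LCP2(y128~U) k_site_off",
        "  lcp2_y145_phos: ZAP70(y493~P) + LCP2(y145~U) -> ZAP70(y493~P) + LCP2(y145~P) k_lcp2",
        "  lcp2_y145_dephos: LCP2(y145~P) -> LCP2(y145~U) k_site_off",
        # long-route adaptor chain LAT -> GRAP2 -> LCP2 -> NCK1
        "  grap2_lat_bind: GRAP2(sh2) + LAT(y191~P) -> GRAP2(sh2!1).LAT(y191~P!1) k_grap2_on",
        "  grap2_lat_unbind: GRAP2(sh2!1).LAT(y191~P!1) -> GRAP2(sh2) + LAT(y191~P) k_grap2_off",
        "  grap2_lcp2_bind: GRAP2(sh3) + LCP2(grap2) -> GRAP2(sh3!1).LCP2(grap2!1) k_g2l_on",
        "  grap2_lcp2_unbind: GRAP2(sh3!1).LCP2(grap2!1) -> GRAP2(sh3) + LCP2(grap2) k_g2l_off",
        "  nck_lcp2_bind: NCK1(sh2) + LCP2(y128~P) -> NCK1(sh2!1).LCP2(y128~P!1) k_ncklcp2_on",
        "  nck_lcp2_unbind: NCK1(sh2!1).LCP2(y128~P!1) -> NCK1(sh2) + LCP2(y128~P) k_ncklcp2_off",
        # WAS Y291 phosphorylation on membrane-anchored NCK1-WAS (long route)
        "  was_long: LCK(y394~P,y505~U) + WAS(y291~U,prs!1).NCK1(csh3!1,sh2!2).LCP2(y128~P!2) -> "
        "LCK(y394~P,y505~U) + WAS(y291~P,prs!1).NCK1(csh3!1,sh2!2).LCP2(y128~P!2) k_was",
        "  was_dephos: WAS(y291~P) -> WAS(y291~U) k_site_off",
        # PLCG1 recruitment to phospho-LCP2 and phosphorylation
        "  plcg1_bind: PLCG1(sh2) + LCP2(y145~P) -> PLCG1(sh2!1).LCP2(y145~P!1) k_plc_on",
        "  plcg1_unbind: PLCG1(sh2!1).LCP2(y145~P!1) -> PLCG1(sh2) + LCP2(y145~P) k_plc_off",
        "  plcg1_y783_phos: ZAP70(y493~P) + PLCG1(sh2!+,y783~U) -> "
        "ZAP70(y493~P) + PLCG1(sh2!+,y783~P) k_y783",
        "  plcg1_y783_dephos: PLCG1(y783~P) -> PLCG1(y783~U) k_site_off",
        "  plcg1_y771_phos: ZAP70(y493~P) + PLCG1(sh2!+,y771~U) -> "
        "ZAP70(y493~P) + PLCG1(sh2!+,y771~P) k_y771",
        "  plcg1_y771_dephos: PLCG1(y771~P) -> PLCG1(y771~U) k_site_off",
        # CSK / PAG1 negative regulation of LCK Y505
        "  pag1_y163_phos: LCK(y505~U) + PAG1(y163~U) -> LCK(y505~U) + PAG1(y163~P) k_pag1",
        "  pag1_y163_dephos: PAG1(y163~P) -> PAG1(y163~U) k_slow_off",
        "  csk_pag1_bind: CSK(sh2) + PAG1(y163~P) -> CSK(sh2!1).PAG1(y163~P!1) k_csk_on",
        "  csk_pag1_unbind: CSK(sh2!1).PAG1(y163~P!1) -> CSK(sh2) + PAG1(y163~P) k_csk_off",
        "  lck_y505_phos: CSK(sh2!+) + LCK(y505~U) -> CSK(sh2!+) + LCK(y505~P) k_y505",
        "  lck_y505_dephos: LCK(y505~P) -> LCK(y505~U) k_y505_off",
        # basally phosphorylated inhibitory sites (ambient kinase activity folded
        # into pseudo-first-order constants)
        "  lck_y192_phos: LCK(y192~U) -> LCK(y192~P) k_basal_on",
        "  lck_y192_dephos: LCK(y192~P) -> LCK(y192~U) k_slow_off",
        "  dok1_y449_phos: DOK1(y449~U) -> DOK1(y449~P) k_basal_on",
        "  dok1_y449_dephos: DOK1(y449~P) -> DOK1(y449~U) k_slow_off",
        "  dok2_y299_phos: DOK2(y299~U) -> DOK2(y299~P) k_basal_on",
        "  dok2_y299_dephos: DOK2(y299~P) -> DOK2(y299~U) k_slow_off",
        # adaptor couplings of the inhibitory sites
        "  dok1_csk_bind: CSK(sh2) + DOK1(y449~P) -> CSK(sh2!1).DOK1(y449~P!1) k_csk_on",
        "  dok1_csk_unbind: CSK(sh2!1).DOK1(y449~P!1) -> CSK(sh2) + DOK1(y449~P) k_csk_off",
        "  dok2_rasa1_bind: RASA1(sh2) + DOK2(y299~P) -> RASA1(sh2!1).DOK2(y299~P!1) k_rasa_on",
        "  dok2_rasa1_unbind: RASA1(sh2!1).DOK2(y299~P!1) -> RASA1(sh2) + DOK2(y299~P) k_rasa_off",
        # LCK-mediated activation of PTPN6 (Y566)
        "  ptpn6_y566_phos: LCK(y394~P,y505~U) + PTPN6(y566~U) -> "
        "LCK(y394~P,y505~U) + PTPN6(y566~P) k_y566",
        "  ptpn6_y566_dephos: PTPN6(y566~P) -> PTPN6(y566~U) k_slow_off",
        # shortcut machinery: without the bind rule below these can never fire
        "  nck_cd3e_unbind: NCK1(nsh3!1).CD3E(prs!1) -> NCK1(nsh3) + CD3E(prs) k_nckcd3e_off",
        "  was_short: LCK(y394~P,y505~U) + WAS(y291~U,prs!1).NCK1(csh3!1,nsh3!2).CD3E(prs!2) -> "
        "LCK(y394~P,y505~U) + WAS(y291~P,prs!1).NCK1(csh3!1,nsh3!2).CD3E(prs!2) k_was",
    ]

    if shortcut_enabled:
        rules += [
            # NCK1 N-SH3 binds the CD3E PRS only while Y188 is unphosphorylated
            # (SH3-PRS binding and ITAM phosphorylation are mutually exclusive)
            "  nck_cd3e_bind: NCK1(nsh3) + CD3E(prs,y188~U) -> "
            "NCK1(nsh3!1).CD3E(prs!1,y188~U) k_nckcd3e_on",
        ]
    if ptpn6_feedback_enabled:
        rules += [
            "  shp1_lck_y192: PTPN6(y566~P) + LCK(y192~P) -> PTPN6(y566~P) + LCK(y192~U) k_shp1",
            "  shp1_pag1_y163: PTPN6(y566~P) + PAG1(y163~P) -> PTPN6(y566~P) + PAG1(y163~U) k_shp1",
            "  shp1_dok1_y449: PTPN6(y566~P) + DOK1(y449~P) -> PTPN6(y566~P) + DOK1(y449~U) k_shp1",
            "  shp1_dok2_y299: PTPN6(y566~P) + DOK2(y299~P) -> PTPN6(y566~P) + DOK2(y299~U) k_shp1",
        ]
    if ptpn6_direct_y505:
        rules += [
            "  shp1_lck_y505: PTPN6(y566~P) + LCK(y505~P) -> PTPN6(y566~P) + LCK(y505~U) k_shp1",
        ]

    obs_lines = _site_observables(roster) + [
        "  Molecules NCK_CD3E_assoc NCK1(nsh3!1).CD3E(prs!1)",
        "  Molecules NCK_LCP2_assoc NCK1(sh2!1).LCP2(y128~P!1)",
        "  Molecules LCK_active LCK(y394~P!?,y505~U!?)",
    ]

    text = "\n".join(
        ["begin parameters"] + p_lines + ["end parameters", "begin molecule types"]
        + mt_lines + ["end molecule types", "begin seed species"] + resolved_seed_lines
        + ["end seed species", "begin observables"] + obs_lines
        + ["end observables", "begin reaction rules"] + rules + ["end reaction rules"]
    ) + "\n"
    spec = parse_model(text)

    # every roster observable must exist in the built model
    have = {o.name for o in spec.observables}
    missing = [e.observable for e in roster.entries if e.observable not in have]
    if missing:
        raise ValueError(f"roster observables missing from model: {missing}")
    return spec


def default_protocol(
    n_runs: int = 40, seed: int = 0, t_eq: float = 100.0, stimulus_copies: int = 150
) -> SimProtocol:
    return SimProtocol(
        t_eq=t_eq,
        grid=(0.0, 5.0, 15.0, 30.0, 60.0),
        n_runs=n_runs,
        seed=seed,
        stimulus={"Ligand": stimulus_copies},
    )


# ---------------------------------------------------------------------------
# perturbations and readouts


def apply_knockdown(spec: ModelSpec, perturbation: Perturbation) -> ModelSpec:
    """Return a copy of the model with the protein's copy number set to zero.

    Rules are untouched; applying the same knockdown twice is a no-op.
    """
    if perturbation.kind != "knockdown":
        raise ValueError(f"unsupported perturbation kind {perturbation.kind!r}")
    return spec.with_seed_count(perturbation.protein, 0)


def relative_timecourse(
    averaged: pd.DataFrame, site: str, eps: float = 0.5
) -> RelativeTimeCourse:
    """Normalize an averaged observable course by its unstimulated baseline.

    Each value is divided by the t=0 value; when the baseline is exactly zero
    the pseudocount ``eps`` is added to numerator and denominator so the
    course remains finite (and equals 1 at t=0 by construction).
    """
    times, values = mean_course(averaged, site)
    if times[0] != 0.0:
        raise ValueError("relative time course requires a t=0 baseline observation")
    v0 = values[0]
    if v0 == 0.0:
        rel = (values + eps) / (v0 + eps)
    else:
        rel = values / v0
    return RelativeTimeCourse(site=site, times=times, values=rel)


def cumulative_auc(
    tc: RelativeTimeCourse, window: tuple[float, float] = (0.0, 60.0)
) -> float:
    """Trapezoidal area under the relative time course over ``window`` (s)."""
    lo, hi = window
    if lo < tc.times[0] or hi > tc.times[-1]:
        raise ValueError(f"window {window} outside grid span")
    ts = [lo] + [t for t in tc.times if lo < t < hi] + [hi]
    vs = np.interp(ts, tc.times, tc.values)
    return float(np.trapezoid(vs, ts))


def scale_to_endpoint(tc: RelativeTimeCourse) -> RelativeTimeCourse:
    """Scale so the value at the final grid time (60 s) equals 1."""
    end = tc.values[-1]
    if end == 0.0:
        raise ValueError("cannot scale a course with zero endpoint")
    return replace(tc, values=tc.values / end)


def half_rise_time(tc: RelativeTimeCourse) -> float:
    """Time of half-maximal rise above baseline, by linear interpolation.

    Returns NaN for courses that never rise above their baseline.
    """
    v0 = tc.values[0]
    vmax = tc.values.max()
    if vmax <= v0:
        return float("nan")
    target = v0 + 0.5 * (vmax - v0)
    for i in range(1, len(tc.times)):
        if tc.values[i] >= target:
            t0, t1 = tc.times[i - 1], tc.times[i]
            y0, y1 = tc.values[i - 1], tc.values[i]
            if y1 == y0:
                return float(t1)
            return float(t0 + (target - y0) / (y1 - y0) * (t1 - t0))
    return float("nan")


def site_class_of(roster: SiteRoster, protein: str, residue: int) -> int:
    """The assigned dynamical class (1, 2 or 3) of a roster site."""
    return roster.get(protein, residue).site_class


def simulate_sites(
    spec: ModelSpec, protocol: SimProtocol, sites: Optional[list[str]] = None,
    eps: float = 0.5,
) -> dict[str, RelativeTimeCourse]:
    """Run the protocol, average the runs and return relative time courses."""
    averaged = average_runs(simulate_runs(spec, protocol))
    names = sites or sorted(averaged["observable"].unique())
    return {s: relative_timecourse(averaged, s, eps=eps) for s in names}
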