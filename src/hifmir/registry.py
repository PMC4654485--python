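"""Canonical registry of the HIF-let-7-AGO1-VEGF network.

The tables below define the two-compartment endothelial-cell model: 47
species, 57 reactions (reversible binding/transport steps counted once) and 91
kinetic parameters.  Species whose compartment is ``nucleus`` correspond to
the nuclear ("N subscript") species of the pathway diagram; degradation
reactions have empty product lists.

Parameter provenance: ``default_median`` marks values pinned to the printed
class medians (mRNA decay 1.2e-3 min^-1, miRNA decay 1e-4 min^-1, protein
decay 2.5e-4 min^-1, translation 3 min^-1, mRNA level 2.8e-5 uM, protein
level 0.08 uM); ``fitted`` marks values recovered by least-squares calibration
against the quantitative anchors of the published validation experiments
(see docs/methods.md and data/calibration_provenance.json).
"""

from __future__ import annotations

from .network import (
    Compartment,
    ModelDefinition,
    Parameter,
    ParameterSet,
    RateLaw,
    Reaction,
    SpeciesDef,
)

CYT = "cytoplasm"
NUC = "nucleus"

COMPARTMENTS = (
    Compartment(CYT, "cytoplasm"),
    Compartment(NUC, "nucleus"),
)

# (id, compartment, role, initial uM, boundary, label)
# Initial concentrations are starting points for normoxic pre-equilibration,
# not the steady state itself; protocols always start from the equilibrated
# state.  miR pools follow the 1e3-1e4 copies/cell estimate at 1 pL.
SPECIES_TABLE = (
    ("O2",                 CYT, "small_molecule", 209.0,   True,  "molecular oxygen (clamped)"),
    ("HIF1A_mRNA",         CYT, "mRNA",           2.8e-5,  False, "HIF-1a mRNA"),
    ("HIF1A_cyt",          CYT, "protein",        6e-4,    False, "HIF-1a protein, cytoplasm"),
    ("PHD2",               CYT, "protein",        1.0,     False, "prolyl hydroxylase 2 (apo)"),
    ("FIH",                CYT, "protein",        0.4,     False, "factor inhibiting HIF (apo)"),
    ("Fe",                 CYT, "small_molecule", 50.0,    False, "Fe(II)"),
    ("DG",                 CYT, "small_molecule", 50.0,    False, "2-oxoglutarate"),
    ("PHD2_Fe_DG",         CYT, "complex",        0.0,     False, "PHD2:Fe:2-OG"),
    ("FIH_Fe_DG",          CYT, "complex",        0.0,     False, "FIH:Fe:2-OG"),
    ("PHD2_Fe_DG_O2",      CYT, "complex",        0.0,     False, "PHD2:Fe:2-OG:O2"),
    ("FIH_Fe_DG_O2",       CYT, "complex",        0.0,     False, "FIH:Fe:2-OG:O2"),
    ("HIF1A_OH",           CYT, "protein",        0.0,     False, "hydroxylated HIF-1a"),
    ("VHL",                CYT, "protein",        0.16,    False, "pVHL E3 ligase"),
    ("CoCl2",              CYT, "perturbant",     0.0,     False, "cobalt chloride"),
    ("CoCl2_PHD2_Fe_DG",   CYT, "complex",        0.0,     False, "CoCl2-inactivated PHD2 complex"),
    ("CoCl2_FIH_Fe_DG",    CYT, "complex",        0.0,     False, "CoCl2-inactivated FIH complex"),
    ("TTP_mRNA",           CYT, "mRNA",           3e-5,    False, "tristetraprolin mRNA"),
    ("TTP",                CYT, "protein",        0.01,    False, "tristetraprolin protein"),
    ("HIF1A_nuc",          NUC, "protein",        1e-3,    False, "HIF-1a protein, nucleus"),
    ("HIF1B",              NUC, "protein",        2.5e-3,  False, "HIF-1b subunit"),
    ("HIF1_complex",       NUC, "complex",        5e-4,    False, "HIF-1 transcription factor complex (incl. CBP/p300)"),
    ("pri_let7",           NUC, "miR_precursor",  1e-5,    False, "primary let-7 transcript"),
    ("pre_let7",           CYT, "miR_precursor",  1e-4,    False, "precursor let-7"),
    ("let7",               CYT, "miR_mature",     1e-4,    False, "mature let-7, free"),
    ("AGO1_mRNA",          CYT, "mRNA",           2.8e-5,  False, "AGO1 mRNA, translatable"),
    ("AGO1_mRNA_pbody",    CYT, "mRNA",           1e-5,    False, "AGO1 mRNA, p-body"),
    ("AGO1",               CYT, "protein",        0.08,    False, "AGO1 protein, free"),
    ("let7_AGO1",          CYT, "complex",        1.6e-3,  False, "let-7:AGO1 RISC, cytoplasm"),
    ("let7_AGO1_nuc",      NUC, "complex",        1e-4,    False, "let-7:AGO1 RISC, nucleus"),
    ("Dicer_mRNA",         CYT, "mRNA",           2.8e-5,  False, "Dicer mRNA, translatable"),
    ("Dicer_mRNA_pbody",   CYT, "mRNA",           1e-5,    False, "Dicer mRNA, p-body"),
    ("Dicer",              CYT, "protein",        0.08,    False, "Dicer protein"),
    ("pre_miR15a",         CYT, "miR_precursor",  2e-6,    False, "precursor miR-15a (lumped VEGF-targeting miRs)"),
    ("miR15a",             CYT, "miR_mature",     1e-4,    False, "mature miR-15a, free"),
    ("miR15a_RISC",        CYT, "complex",        1.5e-2,  False, "miR-15a:AGO1 RISC"),
    ("VEGF_mRNA",          CYT, "mRNA",           5e-6,    False, "VEGF mRNA, translatable"),
    ("VEGF_mRNA_RISC",     CYT, "complex",        1e-5,    False, "VEGF mRNA bound to miR-15a RISC"),
    ("VEGF_mRNA_pbody",    CYT, "mRNA",           2e-5,    False, "VEGF mRNA, p-body"),
    ("VEGF",               CYT, "protein",        0.08,    False, "VEGF protein, intracellular"),
    ("siRNA_TTP",          CYT, "perturbant",     0.0,     False, "siRNA against TTP mRNA"),
    ("siRNA_TTP_mRNA",     CYT, "complex",        0.0,     False, "siRNA:TTP-mRNA duplex"),
    ("siRNA_AGO1",         CYT, "perturbant",     0.0,     False, "siRNA against AGO1 mRNA"),
    ("siRNA_AGO1_mRNA",    CYT, "complex",        0.0,     False, "siRNA:AGO1-mRNA duplex"),
    ("anti_let7",          CYT, "perturbant",     0.0,     False, "let-7 antagonist"),
    ("anti_let7_RISC",     CYT, "complex",        0.0,     False, "antagonist:let-7-RISC complex"),
    ("anti_miR15a",        CYT, "perturbant",     0.0,     False, "miR-15a antagonist"),
    ("anti_miR15a_RISC",   CYT, "complex",        0.0,     False, "antagonist:miR-15a-RISC complex"),
)

# Parameter id -> (value, units, provenance).  Values tagged `fitted` were
# obtained by the calibration described in data/calibration_provenance.json.
PARAMETER_TABLE: dict[str, tuple[float, str, str]] = {
    # --- oxygen sensing / HIF-1a turnover
    "ks_hif_mrna":        (4.1e-8,  "uM/min",    "fitted"),
    "kd_hif_mrna":        (1.2e-3,  "1/min",     "default_median"),
    "a_ttp_hif_mrna":     (20.0,    "1/uM",      "fitted"),
    "kt_hif":             (3.0,     "1/min",     "default_median"),
    "kd_hif_cyt":         (2.5e-4,  "1/min",     "default_median"),
    "kf_phd2_fedg":       (0.1,     "1/(uM*min)", "fitted"),
    "kr_phd2_fedg":       (0.01,    "1/min",     "fitted"),
    "kf_fih_fedg":        (0.1,     "1/(uM*min)", "fitted"),
    "kr_fih_fedg":        (0.01,    "1/min",     "fitted"),
    "kf_phd2_o2":         (0.01,    "1/(uM*min)", "fitted"),
    "kr_phd2_o2":         (1.0,     "1/min",     "fitted"),
    "kf_fih_o2":          (0.01,    "1/(uM*min)", "fitted"),
    "kr_fih_o2":          (1.0,     "1/min",     "fitted"),
    "k_hyd_phd2":         (0.2,     "1/(uM*min)", "fitted"),
    "k_hyd_fih":          (0.05,    "1/(uM*min)", "fitted"),
    "kcat_vhl":           (1.0,     "1/min",     "fitted"),
    "Km_vhl":             (0.01,    "uM",        "fitted"),
    # --- HIF-1 nuclear transport, dimerization, transcription
    "kf_hif_import":      (0.02,    "1/min",     "fitted"),
    "kr_hif_export":      (0.01,    "1/min",     "fitted"),
    "kf_dimer":           (200.0,     "1/(uM*min)", "fitted"),
    "kr_dimer":           (1.0,     "1/min",     "fitted"),
    "Vm_let7":            (1e-4,    "uM/min",    "fitted"),
    "kp21":               (1.5e-3,    "uM",        "fitted"),
    "n_let7":             (2.0,     "dimensionless", "fitted"),
    "basal_let7":         (1e-6,    "uM/min",    "fitted"),
    "Vm_ttp":             (2.4e-6,    "uM/min",    "fitted"),
    "K_ttp":              (1.5e-3,    "uM",        "fitted"),
    "n_ttp":              (2.0,     "dimensionless", "fitted"),
    "basal_ttp":          (6e-8,  "uM/min",    "fitted"),
    "Vm_vegf":            (4.54e-6,    "uM/min",    "fitted"),
    "K_vegf":             (1.66e-3,    "uM",        "fitted"),
    "n_vegf":             (2.4,     "dimensionless", "fitted"),
    "basal_vegf":         (2.77e-7,    "uM/min",    "fitted"),
    "kd_ttp_mrna":        (5e-3,    "1/min",     "fitted"),
    "kt_ttp":             (3.0,     "1/min",     "default_median"),
    "kd_ttp":             (3e-3,    "1/min",     "fitted"),
    # --- let-7 biogenesis and targeting
    "k_drosha":           (0.05,    "1/min",     "fitted"),
    "a_la_feedback":      (5.0,     "dimensionless", "fitted"),
    "K_la_feedback":      (5e-3,    "uM",        "fitted"),
    "kd_pre_let7":        (1.2e-3,  "1/min",     "default_median"),
    "kcat_dicer_let7":    (0.1,     "1/min",     "fitted"),
    "Km_dicer_let7":      (0.01,    "uM",        "fitted"),
    "kd_let7_free":       (1.5e-2,    "1/min",     "fitted"),
    "kf_let7_ago1":       (1.0,    "1/(uM*min)", "fitted"),
    "kr_let7_ago1":       (1e-3,    "1/min",     "fitted"),
    "kd_let7_ago1":       (1.5e-3,    "1/min",     "default_median"),
    "kf_la_import":       (0.02,    "1/min",     "fitted"),
    "kr_la_export":       (0.01,    "1/min",     "fitted"),
    "ks_ago1_mrna":       (1.5e-7, "uM/min",    "fitted"),
    "kd_ago1_mrna":       (1.2e-3,  "1/min",     "default_median"),
    "kt_ago1":            (3.0,     "1/min",     "default_median"),
    "kd_ago1":            (3e-3,    "1/min",     "fitted"),
    "k_pbody_ago1":       (4.0,     "1/(uM*min)", "fitted"),
    "k_pbody_exit_ago1":  (1e-4,    "1/min",     "fitted"),
    "kd_ago1_mrna_pb":    (1.2e-4,  "1/min",     "fitted"),
    "ks_dicer_mrna":      (1.5e-7, "uM/min",    "fitted"),
    "kd_dicer_mrna":      (1.2e-3,  "1/min",     "default_median"),
    "kt_dicer":           (3.0,     "1/min",     "default_median"),
    "kd_dicer":           (3e-3,    "1/min",     "fitted"),
    "k_pbody_dicer":      (3.0,     "1/(uM*min)", "fitted"),
    "k_pbody_exit_dicer": (1e-4,    "1/min",     "fitted"),
    "kd_dicer_mrna_pb":   (1.2e-4,  "1/min",     "fitted"),
    # --- miR-15a arm and VEGF
    "ks_pre_mir15a":      (8.2e-5,  "uM/min",    "fitted"),
    "kd_pre_mir15a":      (1e-2,  "1/min",     "default_median"),
    "kcat_dicer_mir15a":  (0.1,     "1/min",     "fitted"),
    "Km_dicer_mir15a":    (0.01,    "uM",        "fitted"),
    "kd_mir15a_free":     (1.5e-2,    "1/min",     "fitted"),
    "kf_mir15a_ago1":     (0.08,    "1/(uM*min)", "fitted"),
    "kr_mir15a_ago1":     (1e-3,    "1/min",     "fitted"),
    "kd_mir15a_risc":     (7e-3,    "1/min",     "default_median"),
    "kd_vegf_mrna":       (1.2e-3,  "1/min",     "default_median"),
    "a_ttp_vegf_mrna":    (1.0,     "1/uM",      "fitted"),
    "kf_vegf_risc":       (250.0,    "1/(uM*min)", "fitted"),
    "kr_vegf_risc":       (0.03,    "1/min",     "fitted"),
    "k_pbody_vegf":       (6e-3,    "1/min",     "fitted"),
    "k_pbody_exit_vegf":  (5e-4,    "1/min",     "fitted"),
    "kd_vegf_mrna_pb":    (5e-4,  "1/min",     "fitted"),
    "kt_vegf":            (3.0,     "1/min",     "default_median"),
    "kd_vegf":            (2.7e-3,    "1/min",     "fitted"),
    # --- perturbation machinery (zero-dose species in the canonical model)
    "kf_sirna_ttp":       (100.0,   "1/(uM*min)", "user"),
    "kd_sirna_ttp":       (1e-3,    "uM",        "reference_table"),
    "kf_sirna_ago1":      (100.0,   "1/(uM*min)", "user"),
    "kd_sirna_ago1":      (1e-3,    "uM",        "reference_table"),
    "kf_anti_let7":       (100.0,   "1/(uM*min)", "user"),
    "kr_anti_let7":       (1e-4,    "1/min",     "user"),
    "kf_anti_mir15a":     (100.0,   "1/(uM*min)", "user"),
    "kr_anti_mir15a":     (1e-4,    "1/min",     "user"),
    "kf_cocl2_phd2":      (2e-4,    "1/(uM*min)", "fitted"),
    "kr_cocl2_phd2":      (5e-3,    "1/min",     "fitted"),
    "kf_cocl2_fih":       (2e-4,    "1/(uM*min)", "fitted"),
    "kr_cocl2_fih":       (5e-3,    "1/min",     "fitted"),
}

# Reaction tuple layout:
# (id, group, reactants, products, modifiers,
#  kind, {role: param_id}, reverse_kind or None, {role: param_id} or None,
#  description)
_R = lambda *a: a  # noqa: E731 - readability of the long table

REACTION_TABLE = (
    # ------------------------------------------------ oxygen sensing
    _R("v1", "oxygen_sensing", (), (("HIF1A_mRNA", 1),), (),
       "constant", {"k": "ks_hif_mrna"}, None, None,
       "basal HIF-1a transcription"),
    _R("v2", "oxygen_sensing", (("HIF1A_mRNA", 1),), (), ("TTP",),
       "ma1_modulated", {"k": "kd_hif_mrna", "a": "a_ttp_hif_mrna"}, None, None,
       "HIF-1a mRNA decay, destabilized by TTP"),
    _R("v3", "turnover", (), (("HIF1A_cyt", 1),), ("HIF1A_mRNA",),
       "mass_action_1", {"k": "kt_hif"}, None, None,
       "HIF-1a translation"),
    _R("v4", "turnover", (("HIF1A_cyt", 1),), (), (),
       "mass_action_1", {"k": "kd_hif_cyt"}, None, None,
       "basal HIF-1a protein decay"),
    _R("v5", "oxygen_sensing",
       (("PHD2", 1), ("Fe", 1), ("DG", 1)), (("PHD2_Fe_DG", 1),), (),
       "mass_action_2", {"k": "kf_phd2_fedg"},
       "mass_action_1", {"k": "kr_phd2_fedg"},
       "PHD2 + Fe + 2-OG complex assembly (reversible)"),
    _R("v6", "oxygen_sensing",
       (("FIH", 1), ("Fe", 1), ("DG", 1)), (("FIH_Fe_DG", 1),), (),
       "mass_action_2", {"k": "kf_fih_fedg"},
       "mass_action_1", {"k": "kr_fih_fedg"},
       "FIH + Fe + 2-OG complex assembly (reversible)"),
    _R("v7", "oxygen_sensing",
       (("PHD2_Fe_DG", 1), ("O2", 1)), (("PHD2_Fe_DG_O2", 1),), (),
       "mass_action_2", {"k": "kf_phd2_o2"},
       "mass_action_1", {"k": "kr_phd2_o2"},
       "O2 loading of PHD2 complex (reversible)"),
    _R("v8", "oxygen_sensing",
       (("FIH_Fe_DG", 1), ("O2", 1)), (("FIH_Fe_DG_O2", 1),), (),
       "mass_action_2", {"k": "kf_fih_o2"},
       "mass_action_1", {"k": "kr_fih_o2"},
       "O2 loading of FIH complex (reversible)"),
    _R("v9", "oxygen_sensing",
       (("HIF1A_cyt", 1), ("PHD2_Fe_DG_O2", 1)),
       (("HIF1A_OH", 1), ("PHD2_Fe_DG", 1)), (),
       "mass_action_2", {"k": "k_hyd_phd2"}, None, None,
       "PHD2-mediated HIF-1a hydroxylation"),
    _R("v10", "oxygen_sensing",
       (("HIF1A_cyt", 1), ("FIH_Fe_DG_O2", 1)),
       (("HIF1A_OH", 1), ("FIH_Fe_DG", 1)), (),
       "mass_action_2", {"k": "k_hyd_fih"}, None, None,
       "FIH-mediated HIF-1a hydroxylation"),
    _R("v11", "oxygen_sensing", (("HIF1A_OH", 1),), (), ("VHL",),
       "michaelis_menten_catalyzed", {"kcat": "kcat_vhl", "km": "Km_vhl"},
       None, None,
       "VHL-mediated ubiquitination and proteasomal degradation"),
    # ------------------------------------------------ HIF-dependent transcription
    _R("v12", "hif_transcription",
       (("HIF1A_cyt", 1),), (("HIF1A_nuc", 1),), (),
       "mass_action_1", {"k": "kf_hif_import"},
       "mass_action_1", {"k": "kr_hif_export"},
       "HIF-1a nucleocytoplasmic shuttling (reversible)"),
    _R("v13", "hif_transcription",
       (("HIF1A_nuc", 1), ("HIF1B", 1)), (("HIF1_complex", 1),), (),
       "mass_action_2", {"k": "kf_dimer"},
       "mass_action_1", {"k": "kr_dimer"},
       "HIF-1a/HIF-1b dimerization incl. CBP/p300 recruitment (reversible)"),
    _R("v14", "hif_transcription", (), (("pri_let7", 1),), ("HIF1_complex",),
       "hill_activation_basal",
       {"vmax": "Vm_let7", "k": "kp21", "n": "n_let7", "basal": "basal_let7"},
       None, None,
       "HIF-1-driven pri-let-7 transcription (HRE, Hill)"),
    _R("v15", "hif_transcription", (), (("TTP_mRNA", 1),), ("HIF1_complex",),
       "hill_activation_basal",
       {"vmax": "Vm_ttp", "k": "K_ttp", "n": "n_ttp", "basal": "basal_ttp"},
       None, None,
       "HIF-dependent TTP transcription (Hill)"),
    _R("v16", "hif_transcription", (), (("VEGF_mRNA", 1),), ("HIF1_complex",),
       "hill_activation_basal",
       {"vmax": "Vm_vegf", "k": "K_vegf", "n": "n_vegf", "basal": "basal_vegf"},
       None, None,
       "HIF-1-driven VEGF transcription (HRE, Hill)"),
    _R("v17", "turnover", (("TTP_mRNA", 1),), (), (),
       "mass_action_1", {"k": "kd_ttp_mrna"}, None, None,
       "TTP mRNA decay"),
    _R("v18", "turnover", (), (("TTP", 1),), ("TTP_mRNA",),
       "mass_action_1", {"k": "kt_ttp"}, None, None,
       "TTP translation"),
    _R("v19", "turnover", (("TTP", 1),), (), (),
       "mass_action_1", {"k": "kd_ttp"}, None, None,
       "TTP protein decay"),
    # ------------------------------------------------ let-7 arm
    _R("v20", "let7_arm", (("pri_let7", 1),), (("pre_let7", 1),),
       ("let7_AGO1_nuc",),
       "ma1_saturating_activation",
       {"k": "k_drosha", "a": "a_la_feedback", "ka": "K_la_feedback"},
       None, None,
       "combined Drosha processing + XPO-5 export, stimulated by nuclear "
       "let-7:AGO1 (positive auto-regulation)"),
    _R("v21", "turnover", (("pre_let7", 1),), (), (),
       "mass_action_1", {"k": "kd_pre_let7"}, None, None,
       "pre-let-7 decay"),
    _R("v22", "let7_arm", (("pre_let7", 1),), (("let7", 1),), ("Dicer",),
       "michaelis_menten_catalyzed",
       {"kcat": "kcat_dicer_let7", "km": "Km_dicer_let7"}, None, None,
       "Dicer maturation of pre-let-7"),
    _R("v23", "turnover", (("let7", 1),), (), (),
       "mass_action_1", {"k": "kd_let7_free"}, None, None,
       "fast decay of AGO-free let-7"),
    _R("v24", "let7_arm", (("let7", 1), ("AGO1", 1)), (("let7_AGO1", 1),), (),
       "mass_action_2", {"k": "kf_let7_ago1"},
       "mass_action_1", {"k": "kr_let7_ago1"},
       "let-7/AGO1 RISC association (reversible)"),
    _R("v25", "turnover", (("let7_AGO1", 1),), (), (),
       "mass_action_1", {"k": "kd_let7_ago1"}, None, None,
       "slow decay of AGO1-protected let-7 RISC"),
    _R("v26", "let7_arm", (("let7_AGO1", 1),), (("let7_AGO1_nuc", 1),), (),
       "mass_action_1", {"k": "kf_la_import"},
       "mass_action_1", {"k": "kr_la_export"},
       "nuclear shuttling of let-7:AGO1 (reversible)"),
    _R("v27", "turnover", (), (("AGO1_mRNA", 1),), (),
       "constant", {"k": "ks_ago1_mrna"}, None, None,
       "basal AGO1 transcription (hypoxia-independent)"),
    _R("v28", "turnover", (("AGO1_mRNA", 1),), (), (),
       "mass_action_1", {"k": "kd_ago1_mrna"}, None, None,
       "AGO1 mRNA decay"),
    _R("v29", "turnover", (), (("AGO1", 1),), ("AGO1_mRNA",),
       "mass_action_1", {"k": "kt_ago1"}, None, None,
       "AGO1 translation"),
    _R("v30", "turnover", (("AGO1", 1),), (), (),
       "mass_action_1", {"k": "kd_ago1"}, None, None,
       "decay of miR-free AGO1"),
    _R("v31", "let7_arm", (("AGO1_mRNA", 1),), (("AGO1_mRNA_pbody", 1),),
       ("let7_AGO1",),
       "mass_action_2", {"k": "k_pbody_ago1"},
       "mass_action_1", {"k": "k_pbody_exit_ago1"},
       "let-7-RISC routing of AGO1 mRNA into p-bodies (small exit flux)"),
    _R("v32", "turnover", (("AGO1_mRNA_pbody", 1),), (), (),
       "mass_action_1", {"k": "kd_ago1_mrna_pb"}, None, None,
       "slow decay of p-body AGO1 mRNA"),
    _R("v33", "turnover", (), (("Dicer_mRNA", 1),), (),
       "constant", {"k": "ks_dicer_mrna"}, None, None,
       "basal Dicer transcription"),
    _R("v34", "turnover", (("Dicer_mRNA", 1),), (), (),
       "mass_action_1", {"k": "kd_dicer_mrna"}, None, None,
       "Dicer mRNA decay"),
    _R("v35", "turnover", (), (("Dicer", 1),), ("Dicer_mRNA",),
       "mass_action_1", {"k": "kt_dicer"}, None, None,
       "Dicer translation"),
    _R("v36", "turnover", (("Dicer", 1),), (), (),
       "mass_action_1", {"k": "kd_dicer"}, None, None,
       "Dicer protein decay"),
    _R("v37", "let7_arm", (("Dicer_mRNA", 1),), (("Dicer_mRNA_pbody", 1),),
       ("let7_AGO1",),
       "mass_action_2", {"k": "k_pbody_dicer"},
       "mass_action_1", {"k": "k_pbody_exit_dicer"},
       "let-7-RISC routing of Dicer mRNA into p-bodies (small exit flux)"),
    _R("v38", "turnover", (("Dicer_mRNA_pbody", 1),), (), (),
       "mass_action_1", {"k": "kd_dicer_mrna_pb"}, None, None,
       "slow decay of p-body Dicer mRNA"),
    # ------------------------------------------------ miR-15a / VEGF arm
    _R("v39", "mir15a_vegf_arm", (), (("pre_miR15a", 1),), (),
       "constant", {"k": "ks_pre_mir15a"}, None, None,
       "constitutive pre-miR-15a production (not hypoxia-responsive)"),
    _R("v40", "turnover", (("pre_miR15a", 1),), (), (),
       "mass_action_1", {"k": "kd_pre_mir15a"}, None, None,
       "pre-miR-15a decay"),
    _R("v41", "mir15a_vegf_arm", (("pre_miR15a", 1),), (("miR15a", 1),),
       ("Dicer",),
       "michaelis_menten_catalyzed",
       {"kcat": "kcat_dicer_mir15a", "km": "Km_dicer_mir15a"}, None, None,
       "Dicer maturation of pre-miR-15a"),
    _R("v42", "turnover", (("miR15a", 1),), (), (),
       "mass_action_1", {"k": "kd_mir15a_free"}, None, None,
       "fast decay of AGO-free miR-15a"),
    _R("v43", "mir15a_vegf_arm",
       (("miR15a", 1), ("AGO1", 1)), (("miR15a_RISC", 1),), (),
       "mass_action_2", {"k": "kf_mir15a_ago1"},
       "mass_action_1", {"k": "kr_mir15a_ago1"},
       "miR-15a/AGO1 RISC association (reversible)"),
    _R("v44", "turnover", (("miR15a_RISC", 1),), (), (),
       "mass_action_1", {"k": "kd_mir15a_risc"}, None, None,
       "slow decay of AGO1-protected miR-15a RISC"),
    _R("v45", "mir15a_vegf_arm", (("VEGF_mRNA", 1),), (), ("TTP",),
       "ma1_modulated", {"k": "kd_vegf_mrna", "a": "a_ttp_vegf_mrna"},
       None, None,
       "VEGF mRNA decay, destabilized by TTP"),
    _R("v46", "mir15a_vegf_arm",
       (("VEGF_mRNA", 1), ("miR15a_RISC", 1)), (("VEGF_mRNA_RISC", 1),), (),
       "mass_action_2", {"k": "kf_vegf_risc"},
       "mass_action_1", {"k": "kr_vegf_risc"},
       "miR-15a RISC capture of VEGF mRNA (reversible)"),
    _R("v47", "mir15a_vegf_arm",
       (("VEGF_mRNA_RISC", 1),), (("VEGF_mRNA_pbody", 1), ("miR15a_RISC", 1)),
       (),
       "mass_action_1", {"k": "k_pbody_vegf"}, None, None,
       "p-body deposition of RISC-bound VEGF mRNA (RISC recycled)"),
    _R("v48", "mir15a_vegf_arm",
       (("VEGF_mRNA_pbody", 1),), (("VEGF_mRNA", 1),), (),
       "mass_action_1", {"k": "k_pbody_exit_vegf"}, None, None,
       "small p-body exit flux of VEGF mRNA"),
    _R("v49", "turnover", (("VEGF_mRNA_pbody", 1),), (), (),
       "mass_action_1", {"k": "kd_vegf_mrna_pb"}, None, None,
       "slow decay of p-body VEGF mRNA"),
    _R("v50", "turnover", (), (("VEGF", 1),), ("VEGF_mRNA",),
       "mass_action_1", {"k": "kt_vegf"}, None, None,
       "VEGF translation (free mRNA only)"),
    _R("v51", "turnover", (("VEGF", 1),), (), (),
       "mass_action_1", {"k": "kd_vegf"}, None, None,
       "VEGF protein decay"),
    # ------------------------------------------------ perturbation machinery
    _R("v52", "perturbation",
       (("siRNA_TTP", 1), ("TTP_mRNA", 1)), (("siRNA_TTP_mRNA", 1),), (),
       "mass_action_2", {"k": "kf_sirna_ttp"},
       "kd_dissociation", {"kf": "kf_sirna_ttp", "kd": "kd_sirna_ttp"},
       "siRNA silencing of TTP mRNA (Kd-parameterized, reversible)"),
    _R("v53", "perturbation",
       (("siRNA_AGO1", 1), ("AGO1_mRNA", 1)), (("siRNA_AGO1_mRNA", 1),), (),
       "mass_action_2", {"k": "kf_sirna_ago1"},
       "kd_dissociation", {"kf": "kf_sirna_ago1", "kd": "kd_sirna_ago1"},
       "siRNA silencing of AGO1 mRNA (Kd-parameterized, reversible)"),
    _R("v54", "perturbation",
       (("anti_let7", 1), ("let7_AGO1", 1)), (("anti_let7_RISC", 1),), (),
       "mass_action_2", {"k": "kf_anti_let7"},
       "mass_action_1", {"k": "kr_anti_let7"},
       "let-7 antagonist inactivation of let-7 RISC"),
    _R("v55", "perturbation",
       (("anti_miR15a", 1), ("miR15a_RISC", 1)), (("anti_miR15a_RISC", 1),), (),
       "mass_action_2", {"k": "kf_anti_mir15a"},
       "mass_action_1", {"k": "kr_anti_mir15a"},
       "miR-15a antagonist inactivation of miR-15a RISC"),
    _R("v56", "perturbation",
       (("CoCl2", 1), ("PHD2_Fe_DG", 1)), (("CoCl2_PHD2_Fe_DG", 1),), (),
       "mass_action_2", {"k": "kf_cocl2_phd2"},
       "mass_action_1", {"k": "kr_cocl2_phd2"},
       "CoCl2 sequestration of the PHD2 hydroxylation complex"),
    _R("v57", "perturbation",
       (("CoCl2", 1), ("FIH_Fe_DG", 1)), (("CoCl2_FIH_Fe_DG", 1),), (),
       "mass_action_2", {"k": "kf_cocl2_fih"},
       "mass_action_1", {"k": "kr_cocl2_fih"},
       "CoCl2 sequestration of the FIH hydroxylation complex"),
)


def build_model(parameter_overrides: dict[str, float] | None = None) -> ModelDefinition:
    """Assemble the canonical ModelDefinition from the registry tables."""
    species = tuple(
        SpeciesDef(id=sid, compartment=comp, role=role,
                   initial_concentration=ic, boundary=bd, label=label)
        for sid, comp, role, ic, bd, label in SPECIES_TABLE
    )
    params = ParameterSet({
        pid: Parameter(value=v, units=u, provenance=prov)
        for pid, (v, u, prov) in PARAMETER_TABLE.items()
    })
    reactions = []
    for (rid, group, reac, prod, mods, kind, pmap,
         rkind, rpmap, desc) in REACTION_TABLE:
        reactions.append(Reaction(
            id=rid, reactants=tuple(reac), products=tuple(prod),
            modifiers=tuple(mods),
            rate_law=RateLaw(kind, dict(pmap)),
            reverse_rate_law=(RateLaw(rkind, dict(rpmap))
                              if rkind is not None else None),
            group=group, description=desc,
        ))
    model = ModelDefinition(
        compartments=COMPARTMENTS,
        species=species,
        reactions=tuple(reactions),
        parameters=params,
    )
    if parameter_overrides:
        model = model.with_parameters(parameter_overrides)
    return model
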