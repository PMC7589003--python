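"""Default gene-set and metabolite catalogs used by the simulator.

The five metabolic categories carry the canonical set sizes used throughout
the analysis (fatty acid metabolism 63, antioxidant activity 86, oxidative
phosphorylation 144, glycolysis 67, folic acid metabolism 38).  Well-known
mouse symbols head each list; the remainder are synthetic filler symbols
(these catalogs are simulator fixtures, not curated MSigDB contents).  The
67 glycolysis genes are partitioned into six functional sub-pathways from
glucose import/phosphorylation down to the pyruvate-dehydrogenase shift
into oxidative phosphorylation.
"""

from __future__ import annotations

from .containers import GeneSetCatalog

GLUCOSE_IMPORT = [
    "Slc2a1", "Slc2a2", "Slc2a3", "Slc2a4", "Hk1", "Hk2", "Hk3", "Hkdc1", "Gck", "Slc16a1",
]
UPPER_GLYCOLYSIS = [
    "Gpi1", "Pfkp", "Pfkl", "Pfkm", "Pfkfb1", "Pfkfb2", "Pfkfb3", "Pfkfb4",
    "Aldoa", "Aldob", "Aldoc", "Tpi1",
]
LOWER_GLYCOLYSIS = [
    "Gapdh", "Gapdhs", "Pgk1", "Pgk2", "Pgam1", "Pgam2", "Bpgm",
    "Eno1", "Eno2", "Eno3", "Pkm", "Pklr", "Ldha", "Ldhb", "Ldhc",
]
OXPHOS_SHIFT = [
    "Pdha1", "Pdha2", "Pdhb", "Dlat", "Dld", "Pdhx", "Pdk1", "Pdk2", "Pdk3", "Pdp1",
]
GLUCONEOGENESIS = [
    "Fbp1", "Fbp2", "Pck1", "Pck2", "G6pc", "G6pc2", "G6pc3", "Pc", "Got1", "Mdh1",
]
PENTOSE_PHOSPHATE = [
    "G6pdx", "Pgls", "Pgd", "Rpe", "Rpia", "Tkt", "Taldo1", "Prps1", "Prps2", "Tktl1",
]

GLYCOLYSIS_GENES = (
    GLUCOSE_IMPORT + UPPER_GLYCOLYSIS + LOWER_GLYCOLYSIS
    + OXPHOS_SHIFT + GLUCONEOGENESIS + PENTOSE_PHOSPHATE
)  # 67 genes

_FATTY_ACID_REAL = [
    "Cpt1a", "Cpt2", "Acaca", "Acacb", "Fasn", "Scd1", "Scd2", "Acox1", "Acadm",
    "Acadl", "Acads", "Hadha", "Hadhb", "Echs1", "Acly", "Elovl1", "Elovl2",
    "Elovl6", "Acsl1", "Acsl3",
]
_ANTIOXIDANT_REAL = [
    "Sod1", "Sod2", "Sod3", "Cat", "Gpx1", "Gpx2", "Gpx3", "Gpx4", "Txn1", "Txn2",
    "Prdx1", "Prdx2", "Prdx3", "Gsr", "Gclc", "Gclm", "Selenop", "Mt1", "Mt2",
    "Nrf1", "Nfe2l2", "Hmox1",
]
_OXPHOS_REAL = [
    "Ndufa1", "Ndufa2", "Ndufb1", "Ndufs1", "Ndufv1", "Sdha", "Sdhb", "Sdhc", "Sdhd",
    "Uqcrc1", "Uqcrc2", "Cyc1", "Cox4i1", "Cox5a", "Cox5b", "Cox6a1", "Cox7a2",
    "Atp5a1", "Atp5b", "Atp5c1", "Atp5d", "Atp5e",
]
_FOLIC_REAL = [
    "Mthfr", "Dhfr", "Shmt1", "Shmt2", "Mtr", "Mtrr", "Folr1", "Folr2", "Slc19a1",
    "Slc46a1", "Mthfd1", "Mthfd2", "Aldh1l1", "Ftcd", "Tyms", "Gart", "Atic", "Amt",
]


def _fill(real: list[str], prefix: str, size: int) -> list[str]:
    filler = [f"{prefix}{i:03d}" for i in range(len(real) + 1, size + 1)]
    return real + filler


FATTY_ACID_GENES = _fill(_FATTY_ACID_REAL, "Facm", 63)
ANTIOXIDANT_GENES = _fill(_ANTIOXIDANT_REAL, "Aoxg", 86)
OXPHOS_GENES = _fill(_OXPHOS_REAL, "Oxph", 144)
FOLIC_GENES = _fill(_FOLIC_REAL, "Folm", 38)

CELL_CYCLE_GENES = ["Ccnd1", "Ccnb1", "Cdk1", "Cdk4"]
MITO_GENES = ["mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Cytb", "mt-Atp6"]


def metabolic_catalog() -> GeneSetCatalog:
    """The five metabolic categories at their canonical sizes."""
    return GeneSetCatalog(
        {
            "fatty acid metabolism": list(FATTY_ACID_GENES),
            "antioxidant activity": list(ANTIOXIDANT_GENES),
            "oxidative phosphorylation": list(OXPHOS_GENES),
            "glycolysis": list(GLYCOLYSIS_GENES),
            "folic acid metabolism": list(FOLIC_GENES),
        }
    )


def glycolysis_subpathways() -> GeneSetCatalog:
    """Six functional subdivisions of the 67 glycolysis genes."""
    return GeneSetCatalog(
        {
            "glucose_import_phosphorylation": list(GLUCOSE_IMPORT),
            "upper_glycolysis": list(UPPER_GLYCOLYSIS),
            "lower_glycolysis": list(LOWER_GLYCOLYSIS),
            "glycolysis_oxphos_shift": list(OXPHOS_SHIFT),
            "gluconeogenesis": list(GLUCONEOGENESIS),
            "pentose_phosphate": list(PENTOSE_PHOSPHATE),
        }
    )


# ---------------------------------------------------------------------------
# metabolite catalog: name -> (pathway, default KO/WT fold change)

DEFAULT_METABOLITES: dict[str, tuple[str, float]] = {
    # glycolysis: fructose bisphosphate, PEP and pyruvate carry the injected effects
    "D-fructose-1,6-bisphosphate": ("glycolysis", 1.9),
    "phosphoenolpyruvate": ("glycolysis", 1.6),
    "pyruvate": ("glycolysis", 1.4),
    "glucose": ("glycolysis", 1.0),
    "glucose-6-phosphate": ("glycolysis", 1.0),
    "fructose-6-phosphate": ("glycolysis", 1.0),
    "dihydroxyacetone phosphate": ("glycolysis", 1.0),
    "3-phosphoglycerate": ("glycolysis", 1.0),
    "2-phosphoglycerate": ("glycolysis", 1.0),
    "lactate": ("glycolysis", 1.0),
    # fatty acids: one long-chain omega-3 up, saturated species down
    "docosapentaenoic acid": ("fatty acid", 2.2),
    "palmitate": ("fatty acid", 0.7),
    "oleate": ("fatty acid", 0.75),
    "stearate": ("fatty acid", 0.8),
    "linoleate": ("fatty acid", 1.0),
    "myristate": ("fatty acid", 1.0),
    "carnitine": ("fatty acid", 1.0),
    "acetyl-carnitine": ("fatty acid", 1.0),
    "palmitoyl-carnitine": ("fatty acid", 1.0),
    "malonyl-CoA": ("fatty acid", 1.0),
    "arachidonate": ("fatty acid", 1.0),
    "docosahexaenoic acid": ("fatty acid", 1.0),
    # antioxidant and vitamin pools: minimally changed
    "glutathione": ("antioxidant", 1.0),
    "glutathione disulfide": ("antioxidant", 1.0),
    "NADPH": ("antioxidant", 1.0),
    "ascorbate": ("antioxidant", 1.0),
    "taurine": ("antioxidant", 1.0),
    "hypotaurine": ("antioxidant", 1.0),
    "cysteine": ("antioxidant", 1.0),
    "uric acid": ("antioxidant", 1.0),
    "folate": ("vitamin", 1.0),
    "tetrahydrofolate": ("vitamin", 1.0),
    "5-methyltetrahydrofolate": ("vitamin", 1.0),
    "riboflavin": ("vitamin", 1.0),
    "thiamine": ("vitamin", 1.0),
    "pyridoxine": ("vitamin", 1.0),
    "niacinamide": ("vitamin", 1.0),
    "biotin": ("vitamin", 1.0),
    # energy and amino pools
    "ATP": ("other", 1.8),
    "ADP": ("other", 1.0),
    "AMP": ("other", 1.0),
    "NAD+": ("other", 1.0),
    "glutamine": ("other", 1.0),
    "glutamate": ("other", 1.0),
    "alanine": ("other", 1.0),
    "serine": ("other", 1.0),
    "glycine": ("other", 1.0),
    "citrate": ("other", 1.0),
}
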