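"""Download-gated recipes for the genome-scale case studies.

The toy bundles in :mod:`flexcop.cases` run anywhere; the full-scale case
studies need published genome-scale models (GEMs) that this package does
not redistribute.  A :class:`CaseRecipe` documents, as executable data,
exactly how to prepare those models — required model identifiers, reaction
additions/removals and bound edits — and refuses to run until the model
files are present in the given directory.

Recipes (case ids):

* ``pha_consortium`` — sucrose-secreting cyanobacterium (iJB785,
  engineered to co-overexpress the sucrose permease *cscB* and sucrose
  phosphate synthase *sps*) feeding a PHA-producing pseudomonad (iJN1411
  with an invertase added and the nitrate assimilation reactions NTRARx /
  NTRIR2x removed so that nitrogen limitation applies only to the
  consumer).  Sucrose uptake capped at 3.1 mmol/gDW/h (half the glucose
  rate); PHA production capped at 1.83 mmol/gDW/h (the FBA maximum under
  those constraints with PHA as objective, C8 monomer as model PHA).
* ``auxotroph4`` — four iAF1260-derived amino-acid auxotrophs with
  pairwise cross-feeding.  Reported secretion rates as proportion of
  growth rate: arg = 1.5, lys = 2, phe = 1; methionine is quoted both as
  1.6 (figure) and 1.5 (text) in the source — the discrepancy is
  preserved here verbatim rather than resolved.
* ``ltee`` — two initially identical iJO1366 wild-type strains
  (0.01 g/L each) calibrated to glucose uptake 10 mmol/gDW/h with acetate
  secretion 3.7 mmol/gDW/h (growth rate ~0.8 h^-1); the configuration
  space varies glucose/acetate/oxygen uptakes, with an oxygen-stress
  variant capping O2 uptake at 7 mmol/gDW/h.  An optional serial-transfer
  regime (dilute and refresh the medium at a fixed interval) emulates
  batch passaging; its interval and dilution are user choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

__all__ = ["CaseRecipe", "RecipeStep", "real_case_recipe", "RECIPE_CASES"]


@dataclass(frozen=True)
class RecipeStep:
    """One documented model edit: kind in {add_reaction, remove_reaction,
    set_bound, add_coupling, note}."""

    model: str
    kind: str
    detail: str


@dataclass(frozen=True)
class CaseRecipe:
    case_id: str
    description: str
    required_models: tuple[str, ...]  # SBML file names expected on disk
    steps: tuple[RecipeStep, ...]

    def missing_models(self, model_dir: str | Path) -> list[str]:
        model_dir = Path(model_dir)
        return [m for m in self.required_models if not (model_dir / m).exists()]

    def check_models(self, model_dir: str | Path) -> None:
        missing = self.missing_models(model_dir)
        if missing:
            raise FileNotFoundError(
                f"recipe {self.case_id!r} needs model files not found in "
                f"{model_dir}: {missing}. Download the published models "
                "(e.g. from the BiGG database) and place them there; this "
                "package does not redistribute them."
            )

    def load_models(self, model_dir: str | Path):
        """Load and mutate the GEMs per the recipe (download-gated)."""
        self.check_models(model_dir)
        from .stoich import read_model

        return {
            name: read_model(Path(model_dir) / name, dialect="sbml-fbc")
            for name in self.required_models
        }

    def describe(self) -> str:
        lines = [f"case {self.case_id}: {self.description}", "required models:"]
        lines += [f"  - {m}" for m in self.required_models]
        lines.append("steps:")
        lines += [f"  [{s.model}] {s.kind}: {s.detail}" for s in self.steps]
        return "\n".join(lines)


_RECIPES: dict[str, CaseRecipe] = {
    "pha_consortium": CaseRecipe(
        case_id="pha_consortium",
        description=(
            "sucrose-secreting cyanobacterium feeding a PHA-producing "
            "pseudomonad under nitrogen limitation"
        ),
        required_models=("iJB785.xml", "iJN1411.xml"),
        steps=(
            RecipeStep("iJB785", "note", "co-overexpress cscB & sps (sucrose secretion under salt stress)"),
            RecipeStep("iJN1411", "add_reaction", "invertase (extracellular sucrose hydrolysis)"),
            RecipeStep("iJN1411", "remove_reaction", "NTRARx (nitrate reductase; nitrate assimilation removed)"),
            RecipeStep("iJN1411", "remove_reaction", "NTRIR2x (nitrite reductase; nitrate assimilation removed)"),
            RecipeStep("iJN1411", "set_bound", "sucrose uptake lb = -3.1 mmol/gDW/h (1/2 the glucose rate)"),
            RecipeStep("iJN1411", "set_bound", "PHA production rate <= 1.83 mmol/gDW/h (FBA maximum with PHA objective; C8 monomer as model PHA)"),
            RecipeStep("iJN1411", "note", "medium: BG11 with NH4 set by the optimized configuration"),
        ),
    ),
    "auxotroph4": CaseRecipe(
        case_id="auxotroph4",
        description="four amino-acid auxotrophs with ring cross-feeding",
        required_models=("iAF1260.xml",),
        steps=(
            RecipeStep("iAF1260", "remove_reaction", "per strain: biosynthesis of the two amino acids that strain must import"),
            RecipeStep("iAF1260", "add_coupling", "growth-coupled secretion, as proportion of growth rate: arg = 1.5, lys = 2, phe = 1"),
            RecipeStep("iAF1260", "add_coupling", "met secretion quoted as 1.6 (figure) and 1.5 (text) in the source; discrepancy preserved, not resolved"),
        ),
    ),
    "ltee": CaseRecipe(
        case_id="ltee",
        description=(
            "two identical glucose-limited wild types evolving toward a "
            "glucose-specialist/acetate-specialist polymorphism"
        ),
        required_models=("iJO1366.xml",),
        steps=(
            RecipeStep("iJO1366", "set_bound", "glucose uptake lb = -10 mmol/gDW/h (limiting carbon source)"),
            RecipeStep("iJO1366", "set_bound", "acetate secretion calibrated to 3.7 mmol/gDW/h at that uptake (growth rate ~0.8 h^-1)"),
            RecipeStep("iJO1366", "set_bound", "oxygen-stress variant: O2 uptake capped at 7 mmol/gDW/h"),
            RecipeStep("iJO1366", "note", "start: two equal WT strains at 0.01 g/L each; vary per-strain glucose/acetate/O2 uptakes"),
            RecipeStep("iJO1366", "note", "optional serial transfer (dilute + refresh); interval and dilution are user choices"),
        ),
    ),
}

RECIPE_CASES = tuple(_RECIPES)


def real_case_recipe(case_id: str) -> CaseRecipe:
    """Return the documented, executable recipe for a genome-scale case."""
    try:
        return _RECIPES[case_id]
    except KeyError:
        raise ValueError(
            f"unknown case {case_id!r}; available: {sorted(_RECIPES)}"
        ) from None
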