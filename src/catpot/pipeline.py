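"""End-to-end model assembly: reference state -> parameterized RBC model.

Convenience layer tying together the base network, enzyme-module generation,
PERC parameterization and splicing.
"""

from __future__ import annotations

from .core import KineticModel, ModelStructureError
from .enzymes import default_module_spec, generate_module, splice_module
from .network import NetworkConfig, ReferenceState, build_base_model, set_atp_load
from .parameterize import parameterize_module
from .synth import nominal_reference_state

__all__ = ["build_rbc_model", "model_variants"]


def build_rbc_model(
    ref: ReferenceState | None = None,
    modules: tuple[str, ...] = (),
    cfg: NetworkConfig | None = None,
    module_overrides: dict[str, dict[str, float]] | None = None,
) -> KineticModel:
    """Build a parameterized RBC model with the requested enzyme modules.

    ``modules`` names the lumped reactions to replace ("HEX", "PFK", "PYK").
    ``module_overrides`` maps enzyme -> spec-field overrides (used e.g. for
    personalized binding constants).  The returned model sits at the
    reference steady state; any ``cfg.k_atp_scale`` is applied after
    assembly so the perturbation is a step off that state.
    """
    ref = ref or nominal_reference_state()
    cfg = cfg or NetworkConfig()
    module_overrides = module_overrides or {}
    if "HEX" in modules and not cfg.include_rl_shunt:
        raise ModelStructureError(
            "the HEX module needs 2,3-DPG (its dead-end inhibitor); enable the RL shunt")
    scale = cfg.k_atp_scale
    base_cfg = NetworkConfig(cfg.include_rl_shunt, cfg.include_hemoglobin,
                             1.0, cfg.fixed_species)
    model = build_base_model(ref, base_cfg)
    for enzyme in modules:
        spec = default_module_spec(enzyme, **module_overrides.get(enzyme, {}))
        module = generate_module(spec)
        parameterize_module(module, ref)
        model = splice_module(model, module, enzyme)
    model.parameters["modules"] = list(modules)
    if scale != 1.0:
        model = set_atp_load(model, scale)
    return model


def model_variants(ref: ReferenceState | None = None) -> dict[str, KineticModel]:
    """The ten model variants with increasing amounts of regulation.

    Three bases (glycolysis alone; plus RL shunt; plus shunt and hemoglobin)
    and the seven non-empty kinase-module combinations on the full base.
    """
    ref = ref or nominal_reference_state()
    out: dict[str, KineticModel] = {
        "glycolysis": build_rbc_model(
            ref, cfg=NetworkConfig(include_rl_shunt=False, include_hemoglobin=False)),
        "glycolysis+shunt": build_rbc_model(
            ref, cfg=NetworkConfig(include_rl_shunt=True, include_hemoglobin=False)),
        "glycolysis+shunt+hb": build_rbc_model(ref),
    }
    combos = [("PFK",), ("HEX",), ("PYK",), ("PFK", "HEX"), ("PFK", "PYK"),
              ("HEX", "PYK"), ("PFK", "HEX", "PYK")]
    for combo in combos:
        out["glycolysis+shunt+hb+" + "+".join(combo)] = build_rbc_model(ref, combo)
    return out
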