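"""Enumerate the candidate-model family and its parameter bookkeeping.

Builds all 112 candidate models (functional-response family x host
depletion x mortality x rejection x competition tier), prints the
parameter count of a few members, and aggregates the published
selected-model weights into component selection frequencies.
"""

from igparasitoid import ModelSpec, enumerate_models, free_parameters, parameter_count
from igparasitoid.reference import SELECTED_MODEL_WEIGHTS

models = enumerate_models()
print(f"candidate models: {len(models)}")
print(f"first: {models[0]}  (parameters: {parameter_count(models[0])})")

full = ModelSpec.from_string("FRIII_G:NHD:M1:R1:Csup")
print(f"\nfull model {full}: {parameter_count(full)} parameters")
for d in free_parameters(full):
    scope = f"species {d.species}" if d.species else "shared"
    print(f"  {d.name:12s} {scope:10s} prior {d.prior}")

specs = {ModelSpec.from_string(s): w for s, w in SELECTED_MODEL_WEIGHTS.items()}
print("\nselected-model weights aggregate to component frequencies:")
print(f"  no host depletion : {sum(w for s, w in specs.items() if not s.host_depletion):.1f}%")
print(f"  rejection term    : {sum(w for s, w in specs.items() if s.rejection):.1f}%")
print(f"  mortality term    : {sum(w for s, w in specs.items() if s.mortality):.1f}%")
# Each percentage is the share of post-burn-in reversible-jump iterations
# spent in models containing that component.
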