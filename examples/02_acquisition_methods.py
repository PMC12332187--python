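"""Run the three acquisition methods on the same diluted sample.

A spike of target peptides is diluted 1:64 into a constant background and
acquired with DDA, inclusion-list DDA (ilDDA) and RTS-gated targeted DDA
("rtsdda") under paired seeds. Prints per-method scan counts and the cycle
time budget: rtsdda spends scouting sMS2 scans to decide where the expensive
hMS2 scans go, ilDDA spends hMS2 time on every inclusion-list match, and DDA
spends everything on discovery.
"""

from acquisim import acquire, simulate, targets
from acquisim._seeds import derive_seed

GRADIENT = 4.0  # minutes; a short test gradient
seed = 7

background = simulate.generate_peptidome(
    120, derive_seed(seed, "bg"), gradient_min=GRADIENT
)
spike = simulate.generate_peptidome(
    15, derive_seed(seed, "spike"), gradient_min=GRADIENT, source="spike",
    target_fraction=1.0,
)
mixture = simulate.make_dilution_series(background, spike, [1 / 64], seed)[0]

sil = targets.schedule(
    [targets.TargetPeptide(p.sequence, "TAA", rt_pred=p.rt_apex) for p in spike],
    halfwidth_min=1.5, gradient_min=GRADIENT,
)
mixture = simulate.spike_interferents(mixture, sil, per_target=1, seed=seed)
model = simulate.SignalModel(gradient_min=GRADIENT)

for method in acquire.METHODS:
    log = acquire.run_acquisition(
        mixture, sil, acquire.MethodConfig(method), model, seed
    )
    by_type = {}
    for s in log.scans:
        by_type[s.scan_type] = by_type.get(s.scan_type, 0) + 1
    budget = acquire.cycle_budget_report(log)
    hits = sum(e.hit for e in log.events)
    print(f"{method:>7}: scans {by_type} | RTS events {len(log.events)}, hits {hits}")
    print(
        f"         mean ms/cycle: targeted {budget.targeted_ms.mean():6.0f}, "
        f"discovery {budget.discovery_ms.mean():6.0f}, idle {budget.idle_ms.mean():6.0f}"
    )
print(
    "\nhMS2 scans appear only after a real-time-search hit in rtsdda;\n"
    "ilDDA pays hMS2 time for every match, shrinking its discovery budget."
)
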