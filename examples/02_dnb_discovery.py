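"""Dynamic network biomarker discovery on a simulated longitudinal cohort.

Simulates 40 patients sampled at four time points with a planted
12-protein module (3x variance amplification, intra-correlation 0.7),
runs the PLS-DA response contrasts and the four-step DNB identification,
and intersects the two selections into the biomarker panel.
"""

import warnings

from dnbkit import (
    LongitudinalSimConfig,
    build_panel,
    detect_dnb,
    generate_longitudinal_npx,
    run_group_contrasts,
)

cfg = LongitudinalSimConfig(seed=1)
m, truth = generate_longitudinal_npx(cfg)
print(f"Simulated {m.values.shape[0]} proteins x {m.values.shape[1]} samples "
      f"({cfg.n_patients} patients, planted module of {cfg.n_planted})")

contrasts = run_group_contrasts(m)
for name, res in contrasts.items():
    print(f"PLS-DA [{name}]: {len(res['selection'])} proteins with VIP >= 1")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # criteria fallback is expected here
    result = detect_dnb(m, seed=1)

print(f"\nSD filter (2x, every post-baseline time point): "
      f"{len(result['candidates'])} candidates")
for rep in result["reports"]:
    print(
        f"  cluster {rep.cluster_id}: {len(rep.members)} members, "
        f"SDavg={rep.sd_avg:.2f}, PPCi={rep.ppc_in:.2f}, PPCo={rep.ppc_out:.2f}, "
        f"CI={rep.ci:.1f}, criteria={rep.passes_criteria}"
    )
winner = result["winner"]
planted = set(truth["planted"])
members = set(winner.members)
print(
    f"Winning cluster {winner.cluster_id}: recovers "
    f"{len(members & planted)}/{len(planted)} planted proteins, "
    f"{len(members - planted)} background"
)
print("(High CI = inflated variance + tight internal correlation + weak "
      "external correlation: the early-warning signature.)")

panel = build_panel(
    winner.members, contrasts["all"]["selection"],
    contrast="all", cluster_id=winner.cluster_id,
)
print(f"\nDNB panel (DNB members ∩ PLS-DA selection): {len(panel.proteins)} proteins")
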