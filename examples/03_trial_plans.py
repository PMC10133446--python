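"""Generate balanced trial plans and inspect their quota structure.

Each block balances target duration (short/long), target position (3/4),
singleton presence, variant identity, and singleton position (just before
or just after the target) exactly; the order is a seeded shuffle.
"""

import timbrecapture as tc

for exp in ("exp1", "exp2"):
    cfg = tc.load_experiment(exp)
    plan = tc.generate_plan(cfg, seed=42)
    df = tc.plan_to_frame(plan)
    print(f"\n{exp}: {cfg.n_blocks} blocks x {cfg.block_size} = {len(df)} trials")
    print("  trials per condition:")
    for cond, n in df["condition"].value_counts().sort_index().items():
        print(f"    {cond:>6}: {n}")
    sing = df[df["condition"] != "none"]
    print(
        f"  singleton trials: {len(sing)} "
        f"({len(sing) / len(df):.0%} of all trials); "
        f"before/after = {(sing['singleton_pos'] == 'before').sum()}"
        f"/{(sing['singleton_pos'] == 'after').sum()}"
    )
    block1 = df[df["block"] == 1]
    print(
        f"  block 1: short/long = {(block1['target_kind'] == 'short').sum()}"
        f"/{(block1['target_kind'] == 'long').sum()}, "
        f"pos3/pos4 = {(block1['target_pos'] == 3).sum()}"
        f"/{(block1['target_pos'] == 4).sum()}"
    )
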