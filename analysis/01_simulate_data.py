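"""Generate the synthetic study inputs.

Builds a guild-structured extant framework (5 dietary guilds × 10
specimens with texture parameters, diets and metadata), a set of fossil
"unknowns" drawn without guild labels, and a Yule tree with Brownian PC
scores plus stratigraphic ranges for the dietary-evolution analyses.

Writes: results/specimens.csv, results/params.csv, results/diet.csv,
results/fossil_params.csv, results/tree.nwk, results/ranges.csv,
results/example_surface.txt
"""

import sys
from pathlib import Path

import numpy as np

from dmta import (simulate_framework, simulate_strat_ranges, simulate_surface,
                  simulate_tree_and_traits, write_surface, write_tree)
from dmta.simulate import SurfaceRecipe, default_guild_profiles

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# extant framework: the synthetic stand-in for the reptile comparative set
sim = simulate_framework(default_guild_profiles(), n_per_guild=10, seed=SEED)
sim["specimens"].to_csv(OUT / "specimens.csv")
sim["params"].to_csv(OUT / "params.csv")
sim["diets"].to_csv(OUT / "diet.csv")
print(f"framework: {len(sim['specimens'])} specimens, "
      f"{sim['params'].shape[1]} texture parameters, 5 guilds")

# fossil unknowns: parameter vectors drawn between the invertebrate and
# vertebrate guild regimes, with no guild labels attached
rng = np.random.default_rng(SEED + 1)
fossil = simulate_framework(default_guild_profiles(), n_per_guild=4,
                            seed=SEED + 1)
fp = fossil["params"].copy()
fp.index = [f"fossil{i:02d}" for i in range(len(fp))]
fp.to_csv(OUT / "fossil_params.csv")
print(f"fossils:   {len(fp)} unknown specimens (labels withheld)")

# one full-size example scan for the surface pipeline
recipe = SurfaceRecipe(n_scratches=12, n_pits=5, spike_fraction=0.005,
                       seed=SEED)
write_surface(simulate_surface(recipe), OUT / "example_surface.txt")
print(f"surface:   {recipe.nx} x {recipe.ny} points at {recipe.dx} um")

# phylogeny for the dietary-evolution step: 17 fossil taxa
tt, traits, _ = simulate_tree_and_traits(17, seed=SEED)
(OUT / "tree.nwk").write_text(write_tree(tt) + "\n")
simulate_strat_ranges(tt, sampling_span=2.0, seed=SEED).to_csv(
    OUT / "ranges.csv", index=False)
print(f"phylogeny: 17 tips, root age {tt.root_age:.1f} Myr before youngest tip")
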