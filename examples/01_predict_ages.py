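"""Predict DNA-methylation age for individual samples.

Builds a few hand-written pyrosequencing profiles (percent methylation at the
nine registry CpGs), runs every built-in clock on them and prints the
estimated DNAm ages next to the chronological ages.
"""

from cpgclock import builtin_clocks
from cpgclock.clocks import predict_age
from cpgclock.simulate import default_trajectories

# methylation profiles on the generator's mean trajectories, so the expected
# DNAm age of each profile is simply the age it was constructed at
trajectories = default_trajectories()


def profile_at(age: float) -> dict[str, float]:
    return {m: t.alpha + t.beta * age for m, t in trajectories.items()}


samples = {"middle_aged": 45.0, "older_adult": 70.0, "centenarian": 101.0}

clocks = builtin_clocks()
header = f"{'sample':<14}{'age':>6}" + "".join(f"{c.name:>14}" for c in clocks)
print(header)
print("-" * len(header))
for name, age in samples.items():
    row = profile_at(age)
    preds = [predict_age(c, row) for c in clocks]
    cells = "".join(f"{p.dnam_age:>14.1f}" for p in preds)
    print(f"{name:<14}{age:>6.0f}{cells}")

print()
print("Note: predictions outside the clocks' 0-91 y training range carry an")
print("extrapolation flag:")
p = predict_age(clocks[0], profile_at(101.0))
print(f"  {clocks[0].name} at constructed age 101 -> {p.dnam_age:.1f} y, "
      f"extrapolated={p.extrapolated}")
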