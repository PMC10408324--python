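"""Diagnose two synthetic claimants with the packaged published network.

Builds one audiogram typical of noise-induced damage (a 4-kHz notch, worse
on the left) and one typical of pure age-related loss, and prints the
network's probability of noise-induced hearing loss for each.  A
probability at or above 0.5 is a positive diagnosis.
"""

from nihlnet import Audiogram, Individual, classify, default_aahl_table, published_mlp18

table = default_aahl_table()
bundle = published_mlp18()

noise_damaged = Individual(
    id="claimant-1",
    age=52,
    right=Audiogram({1: 10, 2: 15, 3: 35, 4: 60, 6: 50, 8: 30}),
    left=Audiogram({1: 15, 2: 15, 3: 45, 4: 70, 6: 60, 8: 40}),
)
good_hearing = Individual(
    id="claimant-2",
    age=52,
    right=Audiogram({1: 0, 2: 5, 3: 10, 4: 15, 6: 15, 8: 20}),
    left=Audiogram({1: 0, 2: 5, 3: 10, 4: 15, 6: 15, 8: 20}),
)

for ind in (noise_damaged, good_hearing):
    d = classify(bundle, ind, table)
    print(f"{d.id}: P(noise-induced loss) = {d.probability:.3f} -> {d.label}")

print(
    "\nThe first audiogram shows a deep 4-kHz notch with the left ear worse"
    "\nat high frequencies - the classic noise-damage signature the network"
    "\nweights heavily. The second is symmetric and below the age-expected"
    "\nthresholds, so the network clears it. Note the network is trained to"
    "\nfavour sensitivity: borderline audiograms lean positive."
)
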