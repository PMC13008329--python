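"""Clean a barcode table and split it into Pretrain / Seen / Unseen.

Builds a small synthetic corpus, runs the cleaning rules (non-ACGT -> N,
trailing-N truncation, length/ambiguity filters, deduplication), then
assigns every record to a partition. The printed report shows how many
records each rule removed; the partition summary shows the record /
species / genus counts per partition.
"""

from barcodelm import PartitionConfig, SimConfig, assign_partitions, generate, preprocess

records = generate(SimConfig(n_orders=3, genera_per_order=5, species_per_genus=6, seed=11))
print(f"generated {len(records)} raw records")

cleaned, report = preprocess(records)
print("cleaning report:", report.as_dict())

assignment = assign_partitions(cleaned, PartitionConfig(seed=0))
for label, stats in assignment.summary.items():
    print(f"{label:>10}: {stats['records']:5d} records, "
          f"{stats['species']:4d} species, {stats['genera']:3d} genera")

# Seen species get 20-50 records each, split 70/20/10; rare species of
# Seen genera land in Unseen (at most 20 records per genus); everything
# else - including every record of a genus with no well-sampled species -
# feeds self-supervised pretraining.
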