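"""Generate a synthetic study fixture with known ground truth.

Builds a compact two-subpopulation inbred panel (Balding-Nichols structure
with local LD), plants cis/trans eQTLs, splice QTLs, co-expression modules
and selective-sweep windows, and writes everything as VCF/TSV/BED/JSON.
"""

from heritex import SimulationConfig, build_default_fixture, write_fixture_set

fx = build_default_fixture(
    seed=42,
    config=SimulationConfig(n_genotypes=100, n_markers=2000, seed=42),
    n_genes=300, n_introns=60, n_cis=10, n_trans=3,
    n_modules=2, module_size=25, n_sqtl=8,
)

paths = write_fixture_set(fx, "example_fixture")

g = fx.genotypes
print(f"genotypes : {g.n_samples} inbred lines x {g.n_markers} markers")
print(f"subpops   : {fx.labels.value_counts().to_dict()}")
print(f"expression: {fx.expression.fpkm.shape[0]} samples x {fx.expression.fpkm.shape[1]} genes")
print(f"planted   : {len(fx.truth.planted_cis)} cis-eQTL, {len(fx.truth.planted_trans)} trans-eQTL,"
      f" {len(fx.truth.planted_modules)} modules, {len(fx.truth.planted_sweeps)} sweeps,"
      f" {len(fx.truth.planted_splice_qtl)} sQTL")
print(f"MAF floor holds for {100 * (g.maf() >= 0.05).mean():.1f}% of markers")
print("files:")
for name, p in paths.items():
    print(f"  {name:13s} {p}")
# The truth table records every planted effect, so downstream examples can
# score recovery against it.
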