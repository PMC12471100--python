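# retroburst

Structural annotation and evolutionary-dynamics statistics for LTR
retrotransposon family bursts, together with a ground-truth burst simulator
that makes every downstream stage testable without external genome
downloads.

The pipeline covers:

- **Simulation** (`retroburst.simulate`) — master-copy expansion of an LTR
  element template (TGT...ACA termini, PBS reverse-complementary to a tRNA
  3' end, codon-structured ORF) into host contigs, duplicating the 4-bp
  target site at every insertion. Per-insertion truth records, the true
  multiple alignment, and the genealogy in Newick are returned. Neutral
  star/coalescent alignments and a master-succession (nested sub-burst)
  scenario are also provided.
- **Annotation** (`retroburst.annotate`) — delimits full-unit elements
  around seed loci inside ~15 kb windows: exact k-mer self-seeding, direct
  repeat extension, boundary snapping to TGT...ACA termini and confirmation
  by identical 4-bp target site duplications.
- **Consensus & families** (`retroburst.consensus`) — column-plurality
  consensus, longest-ATG-ORF prediction, single-linkage family clustering
  at a 70% identity threshold, and primer-binding-site matching against a
  tRNA library.
- **Evolutionary statistics** (`retroburst.evostats`) — pairwise Ts/Tv
  counts, p and closed-form F84 distances, the entropy-based substitution
  saturation index with simulated critical values (symmetric and pectinate
  topologies), Tajima's D and Fu & Li's D*/F* (plus outgroup variants) with
  beta-approximate and coalescent-simulated p-values, within/between-group
  p-distances with a 90% site-coverage filter and column-bootstrap SEs,
  sliding-window divergence with robust peak calling, and the
  Ts/Tv-versus-distance saturation regression.
- **Counting dN/dS** (`retroburst.dnds`) — uncorrected synonymous /
  nonsynonymous change counting on codon alignments with pairwise gap/stop
  removal, equal-weight averaging over minimal non-stop mutational
  pathways for multi-hit codons, per-family ratio distributions, and
  Mann-Whitney group comparisons.
- **Trees** (`retroburst.phylo`) — neighbor joining with negative-branch
  clamping, column-bootstrap bipartition supports, and rooted
  monophyly/paraphyly/polyphyly classification of copy groups.

## CLI

The `rbd` command chains the stages; all stages are deterministic given
`--seed`:

```sh
# simulate two families of ten copies each, with ground truth
rbd --seed 1 --out-dir out simulate --families 2 --copies-per-family 10

# delimit elements around seed loci (BED) in a genome FASTA
rbd --seed 1 --out-dir out annotate --genome out/genome.fasta --seeds seeds.bed

# consensus, ORF, PBS and (optionally) identity clustering
rbd --out-dir out consensus --alignment out/copies_aligned.fasta \
    --groups out/groups.tsv --trna out/trna.fasta --ltr5-end 300

# saturation, neutrality, p-distance and sliding-window reports
rbd --seed 1 --out-dir out stats --alignment out/copies_aligned.fasta \
    --groups out/groups.tsv

# counting dN/dS on a codon alignment (e.g. the RT region)
rbd --out-dir out dnds --alignment out/rt_aligned.fasta --groups out/groups.tsv

# NJ + bootstrap tree and monophyly classification
rbd --seed 1 --out-dir out tree --alignment out/copies_aligned.fasta \
    --groups out/groups.tsv

# everything end-to-end on freshly simulated data
rbd --seed 1 --out-dir out all
```

Global flags: `--config` (flat TOML, overridden by CLI flags), `--seed`,
`--out-dir`, `--log-level`. Inputs and outputs are plain text (FASTA, TSV,
BED, JSON, Newick).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exhaustive
pathway-enumeration oracles for the codon counting, selection-strength
(omega) parameter recovery, neutrality-test calibration against formula
oracles and neutral/star simulations, exact-boundary annotator recovery on
simulated genomes, saturation-index behavior, the F84 closed form versus a
numerical ML oracle, recombination-screen positive/negative controls, and
tree/monophyly checks including the nested sub-burst (paraphyletic parent)
pattern.

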