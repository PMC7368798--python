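# Methods

## Segregation model

`pedseg` treats one biallelic, normalized site at a time; sites are
filtered independently and candidate sets are simple intersections of
per-member constraints.  Two inheritance models are evaluated, separately
or as a union ("both"):

**Recessive homozygous.**  The index and every affected relative must be
homozygous for the alternate allele; each unaffected parent of the index
must be a heterozygous obligate carrier; unaffected relatives may carry one
allele but must not be homozygous.  This is the classical fully penetrant
autosomal recessive pattern.

**De novo heterozygous.**  The index and affected relatives must carry the
alternate allele (het or hom); parents and unaffected relatives must be
homozygous reference.  With unaffected parents and full penetrance, a
heterozygous candidate in the index cannot have been inherited, so the
heterozygous trio stratum is interpreted as de novo.  An optional
"inherited-het" relaxation (parents and unaffected members may be
heterozygous carriers) is provided for sensitivity analysis of
incomplete-penetrance scenarios; it is off by default.

Roles are derived from the pedigree: the index's parents act as
transmitting parents whenever they are not themselves affected (an
affected parent is constrained as an affected relative instead); everyone
else is constrained by affection status; members with unknown affection
are carried through I/O but impose no constraint.  The sibship analysis
tests the index plus its siblings (sharing at least one parent;
half-siblings included) and never consults parental genotypes even when
present.

**Zygosity on the sex chromosomes.**  Male calls on X and Y are
hemizygous and are classified homozygous-alt whenever they carry the
alternate allele, including diploid-coded het calls emitted by callers on
X.  Pseudoautosomal regions are not special-cased; this blanket rule is a
documented simplification.  Mitochondrial sites are excluded from
segregation (heteroplasmy breaks the diploid zygosity model).

**Missing genotypes.**  A no-call, or any call below the depth threshold,
is downgraded to MISSING.  MISSING is non-informative by default: the
member's constraint is skipped, so coverage gaps in relatives do not
discard candidates.  The exception is the index: candidacy is anchored on
an informative index genotype, both because an index no-call supports
nothing and because the homozygous/heterozygous stratification is keyed on
the index's zygosity.  A strict mode treats MISSING as incompatible
everywhere.

## Site and call filters

| parameter | default | meaning |
|---|---|---|
| `max_af` | 0.015 | population AF ceiling, strict `<` (a site at exactly 1.5% fails) |
| `min_depth` | 20 | per-call depth floor, inclusive (20x passes) |
| `require_pass` | true | drop sites whose FILTER is anything but PASS / "." |
| `af_missing_policy` | retain | sites without an AF annotation are kept (rare by construction) |
| `depth_scope` | call | depth enforced per call; `site` drops the whole site when any tested member fails |

The AF source is a single configurable INFO key (default `AF`);
consequence terms come from a configurable key (default `CSQ`) parsed as a
comma/pipe-delimited term list.  Beyond FILTER status and depth no other
quality filter is applied.

## Annotation

A variant is coding or noncoding according to the class of its most severe
consequence term under a fixed built-in severity ranking modelled on the
standard sequence-ontology hierarchy.  Everything from transcript ablation
down to synonymous maps coding; splice-region, UTR, intronic and
intergenic terms map noncoding; unknown terms rank least severe and map
noncoding.  The exonic/intronic dichotomy motivates classifying
splice-region and UTR as noncoding while synonymous stays coding; both the
order and the per-term classes are overridable by constructing a custom
`SeverityRanking`.  When no consequence terms are present, an optional
interval gene model (4-column TSV, 1-based inclusive coordinates to match
VCF; a zero-based switch accepts BED-style starts) decides by position;
with neither, the variant is noncoding.

## VCF and PED conventions

Multi-allelic sites are split into one record per alternate allele with
per-sample genotypes recoded against the retained allele; a genotype
carrying a *different* alternate allele is recoded as missing — it neither
supports nor excludes segregation of the retained allele and no carrier is
ever invented.  Coordinates are 1-based and never shifted; indel left
normalization is assumed done upstream.  FILTER "." is read as pass.
Hemizygous calls round-trip as single-allele genotypes.  PED files use the
common 6-column dialect plus an optional 7th proband-flag column; without
the flag, the index is the first affected member in file order — a
deterministic stand-in for the clinical convention of listing the proband
first.

## The simulator

The generator is built to make the segregation filters testable
end-to-end, with the following structure:

* **Sites are independent** — no linkage, no recombination map.  Linkage
  changes the correlation between per-site outcomes, not per-site
  segregation compatibility; replicate medians absorb the extra variance
  that real LD would add.  Consequently the simulator cannot express runs
  of homozygosity, and tests passing here say nothing about ROH-based
  methods.
* **Population sites** (default 100,000): database AF log-uniform on
  [1e-4, 0.015], founders drawn at Hardy–Weinberg equilibrium at that AF.
  AF values are snapped to 4 decimals stored as 32-bit floats so INFO/AF
  survives VCF text round-trips bit-for-bit.
* **Family-enriched sites** (default 1,000): all pedigree founders draw
  from a common local allele pool (frequency 0.3) while the *database* AF
  is still drawn from the rare spectrum.  These model alleles common in an
  endogamous community but invisible to population databases — the
  variants that frequency filters cannot remove and family genotypes can.
* **Pedigree**: one great-grandparental couple whose two children (with
  married-in spouses) produce the father and mother, who are therefore
  first cousins; their children have expected inbreeding coefficient
  F = 1/16.  Founder-allele labels ride along through transmission, so
  offspring autozygosity is an emergent, measurable property (checked
  against the closed-form 1/16 within 3 standard errors).  Templates:
  octet (index + parents + 5 sibs; default 2 affected + 3 unaffected
  ordered affected, unaffected, unaffected, affected, unaffected) and
  quintet (index + parents + 2 sibs; default 1 affected + 1 unaffected,
  chosen so the default sibship family exercises both the shared and the
  non-shared constraint).  The index is male (exercising X hemizygosity);
  sibling sexes alternate deterministically from the seed.
* **Transmission**: fair Mendelian sampling; sons receive their single X
  from the mother; male X calls are emitted as true single-allele
  genotypes.
* **De novo mutations**: Poisson(1) per offspring across random sites.
* **Genotype error** (default 0.5% per call): a call flips to a uniformly
  chosen different diploid code (male X: the other hemizygous code).
  Errors in a homozygous-reference background are what create the
  pseudo-de-novo candidates that parents, and then siblings, eliminate —
  a deliberate, realistic driver of the reduction curve.
* **Depth**: Poisson per call at the profile mean (90x exome profile, 30x
  genome profile), with 1% of calls drawn at mean 10x to exercise the 20x
  rule.
* **Planted causal variant**: one autosomal coding site is overwritten —
  error-free, depth forced ≥ 20, database AF below the ceiling — with the
  pattern homozygous-alt in index and affected sibs, het in both parents,
  unaffected sibs carriers with probability 2/3 (the conditional carrier
  probability for an unaffected child of two carriers) else homozygous
  reference.  The allele is carried down one great-grandparental line when
  ancestors are emitted.  With genotype error disabled it is retained by
  every strategy at every step.

Identical configuration and seed give byte-identical VCF/PED output.

## Numerical and design choices

* Percent drops are `100 × (1 − total_k / total_{k−1})`; a zero previous
  total defines a drop of 0.
* Step labels follow the tested-individual count (Index, Trio, Quartet, …
  Octet); an incomplete trio (index + one parent) is labelled Trio, and a
  second step that is not a parent is labelled by its count.
* Replicate aggregation averages counts per step (exact means in JSON,
  half-up integer rounding for display) and summarizes per-step drops as
  median/min/max across replicates, computing drops within each replicate
  first.
* The incremental engine precomputes a per-site, per-member zygosity
  matrix once and evaluates each step as a vectorized constraint
  intersection; a brute-force per-variant per-member evaluation is kept in
  the test suite as an independent oracle.  Nestedness of the step-wise
  candidate sets (adding a member only adds constraints) holds by
  construction and is property-tested.
* Headline summaries use 20 replicates with consecutive seeds; this keeps
  the full default-size analysis around a minute while the median is
  stable to well under the margins being tested.

## Known limitations

* No compound-heterozygote pairing, no phasing, no linkage or LOD
  support, no pathogenicity (ACMG) classification — candidate sets are
  purely segregation- and frequency-based.
* The trio-vs-sibship comparison reports coding recessive counts plus the
  shared-homozygote counts among all-affected and all-unaffected sibling
  sets; with the default simulator conditions the trio count typically
  *exceeds* the sibship count, because at a founder-pool frequency of 0.3
  heterozygous parents are the modal configuration and the parental-het
  constraint removes less than the affected-sibling-homozygous constraint.
  Empirically the opposite ordering has been reported in consanguineous
  cohorts; reproducing it would require a founder pool dominated by
  higher-frequency alleles (or counting heterozygous sibship candidates),
  which the default conditions deliberately do not assume.
* Uniform per-site error and depth models; no allele-balance or
  genotype-quality dimension.
* The X rule ignores pseudoautosomal regions; mitochondrial inheritance is
  out of scope.
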