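# tinx

Literature-based prioritization of drug targets, built for the problem that
most of the proteome is understudied: the proteins with the most publications
attract ever more, while potentially disease-relevant "dark" targets (Tdark in
the Target Development Level classification) stay invisible. `tinx` turns
text-mined publication mentions of protein targets and Disease Ontology terms
into two complementary bibliometric scores per (target, disease) association
and ranks associations on their Pareto fronts, so that a researcher can find
targets that are both little-studied and strongly tied to a disease.

## Scores

For a publication *k*, let *T_k* and *D_k* be the numbers of distinct targets
and diseases tagged in it. Over all publications mentioning target *i*:

```
novelty      N_i  = 1 / Σ_k (1 / T_k)
```

High novelty means little has been published about the target (a paper
mentioning many targets counts fractionally toward each). Over all
publications supporting the association of target *i* with disease *j*:

```
importance   I_ij = Σ_k 1 / (T_k · D_k)
```

High importance means much has been published tying the target to the
disease. A disease-side novelty is defined symmetrically over *D_k*.

Publication support is propagated up the Disease Ontology `is_a` hierarchy as
*publication sets*: a paper mentioning a disease supports all of that
disease's ancestors too, but only once per paper, even if it mentions several
siblings. Associations for a query are then ordered by non-dominated-solution
(NDS) rank over (novelty, importance): rank 1 is the Pareto front, rank 2 is
the front after removing rank 1, and so on, with the top 300 shown by default.

## Worked example

The package ships a deterministic 4-publication demonstration corpus
(3 targets A/B/C annotated Tclin/Tbio/Tdark; diseases X and Y under a shared
ontology parent Z):

```
tinx fixture --outdir demo/in
tinx compute --mentions demo/in/mentions.tsv --obo demo/in/disease.obo \
             --targets demo/in/targets.tsv --pubmeta demo/in/pubmeta.tsv \
             --outdir demo/out
cat demo/out/associations.tsv
```

```
target_id  symbol  tdl    idg_family  disease_id    disease_name  importance  target_novelty  disease_novelty  n_pubs
A          GENE1   Tclin  GPCR        DOID:0000010  disease Z     1.25        0.6666666666666666  0.4          2
A          GENE1   Tclin  GPCR        DOID:0000011  disease X     1.25        0.6666666666666666  0.6666666666666666  2
A          GENE1   Tclin  GPCR        DOID:0000012  disease Y     0.25        0.6666666666666666  0.6666666666666666  1
B          GENE2   Tbio   Kinase      DOID:0000010  disease Z     0.75        1.0                 0.4          2
B          GENE2   Tbio   Kinase      DOID:0000011  disease X     0.25        1.0                 0.6666666666666666  1
B          GENE2   Tbio   Kinase      DOID:0000012  disease Y     0.75        1.0                 0.6666666666666666  2
C          GENE3   Tdark  IonChannel  DOID:0000010  disease Z     0.5         0.6666666666666666  0.4          1
C          GENE3   Tdark  IonChannel  DOID:0000012  disease Y     0.5         0.6666666666666666  0.6666666666666666  1
```

Reading the first row: target A appears in two publications, one tagging A
alone with one disease (contributing 1/(1·1) = 1) and one tagging two targets
and two diseases (contributing 1/(2·2) = 0.25), so I = 1.25; its novelty is
1/(1/1 + 1/2) = 2/3. The DOID:0000010 rows exist only through ontology
propagation — that parent term is never tagged directly — and the paper
mentioning both of its children counts once toward it.

Browsing the parent disease ranks its three targets:

```
tinx query --outdir demo/out --disease DOID:0000010
```

```
target_id  ...  importance  target_novelty  nds_rank  within_rank_order  log_novelty  log_importance
A          ...  1.25        0.666667        1         0                  -0.176091     0.096910
B          ...  0.75        1.000000        1         1                   0.000000    -0.124939
C          ...  0.50        0.666667        2         0                  -0.176091    -0.301030
```

A and B are mutually non-dominated (A has higher importance, B higher
novelty), so both sit on Pareto front 1; C is dominated by A in both
coordinates and falls to front 2. The command also writes each association's
supporting articles, newest first. `tinx export-json` emits the same data as
versioned JSON documents, and `tinx simulate --seed N` generates random
corpora with a known ground truth for testing.

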