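# genegames

Game-theoretic gene ranking on microarray co-expression networks.

Differential-expression statistics score genes one at a time; they say
little about the *joint* role genes play in a disease condition.
`genegames` treats a case/control microarray experiment as a cooperative
game and ranks genes by two allocation rules:

- the **Link Relevance Index (LRI)** — the position value of a network
  game defined on the gene co-expression network, which credits each
  gene for the links it sustains;
- the classical **microarray-game Shapley value**, the coalition-based
  baseline it is compared against.

It is aimed at bioinformaticians prioritising candidate disease genes
from two expression matrices (normal and disease tissue over the same
gene set), and at game-theory researchers who want a tested reference
implementation of link-based allocation rules on co-expression networks.

## The model

Starting from a reference matrix $A^{S_R}$ and a disease matrix
$A^{S_D}$ (genes × samples), the pipeline is:

1. **Discriminant.** Entry $(i,j)$ of the disease matrix is zeroed when
   it lies within $[\min_h A^{S_R}_{ih},\ \max_h A^{S_R}_{ih}]$ over all
   reference samples $h$, and kept verbatim otherwise, giving the
   abnormal-expression matrix $R$.
2. **Similarity.** $s_{ij} = |\mathrm{cor}(R_{i\cdot}, R_{j\cdot})|$,
   the absolute Pearson correlation of gene rows (0 where undefined).
3. **Hard threshold.** Link $ij$ is present in the co-expression
   network $g^E$ iff $s_{ij} \ge \tau$ (signum adjacency; ties keep the
   link).
4. **Network game.** Each connected gene $i$ has support
   $g^E_i$ = its incident links. The value of any network $g$ is

   $$v(g) = \frac{|\{i : \emptyset \ne g^E_i \subseteq g\}|}{n(g^E)},$$

   the fraction of connected genes whose whole support lies in $g$.
5. **LRI.** The position value of $(N, v, g^E)$: each link earns its
   Shapley value over the link set and splits it between its endpoints.
   On the full network it reduces to the degree closed form

   $$F_i = \frac{1}{2\,n(g^E)}\Bigl(1 + \sum_{j \sim i} \frac{1}{\deg(j)}\Bigr),$$

   so a gene is salient when it is connected to many sparsely connected
   partners. Isolated genes score 0.
6. **Shapley baseline.** The Boolean abnormality matrix defines a
   TU-game whose value is the fraction of arrays with support inside a
   coalition; its Shapley value is
   $\Phi_i = \frac{1}{|S_D|}\sum_{j\,:\,i \in sp(j)} 1/|sp(j)|$.

All game-theoretic scores are computed in exact rational arithmetic;
exponential-time formulas (coalition/subnetwork enumeration) exist only
as verification oracles for the closed forms.

## Worked example

The bundled five-gene demonstration experiment (4 normal, 3 disease
samples) runs end-to-end in milliseconds:

```python
from genegames.datasets import write_five_gene_tables
from genegames.pipeline import PipelineConfig, run_pipeline

ref, dis = write_five_gene_tables("demo")
run_pipeline(PipelineConfig(reference_path=ref, disease_path=dis,
                            out_dir="demo_out", tau=0.8))
```

At τ = 0.8 the co-expression network is `{12, 23, 45}` (`edges.tsv`),
and `score_table.tsv` reads:

```
gene_id  lri   shapley   lri_rank  shapley_rank
2        0.3   0.22222   1         1
4        0.2   0.19444   2         4
5        0.2   0.19444   3         5
1        0.15  0.19444   4         2
3        0.15  0.19444   5         3
```

Gene 2 tops both rankings: it bridges genes 1 and 3 (LRI
6/20 = 0.3 — it sustains two links whose partners have no other
connections), and it sits in two of the three array supports. The LRI
vector (3/20, 6/20, 3/20, 4/20, 4/20) sums to 1 = v(g^E): the whole
network value is distributed over the genes.

The same pipeline is available from a shell:

```sh
genegames build-net --reference demo/reference.tsv --disease demo/disease.tsv \
    --tau 0.8 --out edges.tsv
genegames score --edges edges.tsv --out scores.tsv
genegames verify --edges edges.tsv   # position-value oracle + axiom checks
```

For a real study, point `build-net` at your own two TSV matrices
(header row of sample ids, first column of gene ids) and raise τ
(0.9 is a common choice for microarray co-expression work); then
`compare` counts top-k overlaps between the LRI and Shapley rankings.

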