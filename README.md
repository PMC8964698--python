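# bewindow

Quantification of CRISPR base-editor outcomes — and of editing-window
focusing by editor-attenuating agents — from paired-end amplicon deep
sequencing.

Base editors (BEs) install single-base substitutions without double-strand
breaks: cytidine base editors (CBEs) convert C•G→T•A, adenine base editors
(ABEs) convert A•T→G•C.  Editing is position-dependent along the 20-nt
protospacer (PAM at positions 21–23): canonical CBEs edit efficiently in
the positions 4–8 window, ABE7.10 in 4–7, with unwanted bystander edits
elsewhere.  Weak Cas9 inhibitors such as phage-derived G8P_PD peptides can
preferentially suppress that out-of-window activity.  `bewindow` measures
all of this from FASTQ:

- per-position intended-conversion frequencies **f(p)** over the
  protospacer, from quality-filtered, overlap-merged, realigned reads;
- the per-position **inhibition rate** between a control and a treated
  (inhibitor) condition, `IR(p) = 1 − f_treated(p) / f_control(p)`;
- the window-focusing contrast: **selectivity fold**
  `mean IR(out-of-window) / mean IR(on-target)` with a two-tailed
  Student's *t* test between the two groups of IR values;
- **indel frequency** (reads with ≥1 inserted/deleted base in the
  protospacer / total mapped reads);
- **allele-level outcomes**: every fully observed protospacer sequence is
  classified as perfectly edited (intended conversions only), unedited,
  imperfectly edited, or indel-carrying, and conditions are compared by
  perfect-of-total and perfect-of-edited fractions.

A truth-known simulator (`bewindow.simulate`) generates window-shaped
editing, inhibitor attenuation, indels, and Illumina-like overlapping read
pairs with quality strings, so the entire pipeline is testable without any
sequencing download.

## Worked example

Simulate a control and an inhibitor-treated sample of an A3A-like CBE
locus (the `focused-inhibitor` preset attenuates out-of-window editing
with IR 0.9 and on-target editing with IR 0.1 — a construction selectivity
fold of 9):

```bash
bewindow simulate focused-inhibitor --out demo --condition control --coverage 2000
bewindow simulate focused-inhibitor --out demo --condition treated --coverage 2000
```

Describe the run in `demo/run.yaml`:

```yaml
targets:
  - name: demo_cbe
    amplicon_seq: GGAGTTTCCATCCCGTCAGCAAGGACAGTTCTGCCACCGTCATGCTACTGAGGTGTTTGACACCGAGCTTGACCTTGGACCTTAAAGGCTCTGCGTGGTAGATCTAAGTGAACGGTCTTG
    protospacer_start: 30
    protospacer_strand: "+"
    editor: CBE
    intended_positions: [4]
samples:
  - {id: ctrl, target: demo_cbe, condition: control, replicate: 1,
     r1: focused-inhibitor.control.R1.fastq, r2: focused-inhibitor.control.R2.fastq}
  - {id: g8p,  target: demo_cbe, condition: treated, replicate: 1,
     r1: focused-inhibitor.treated.R1.fastq, r2: focused-inhibitor.treated.R2.fastq}
output_dir: out
```

then compare conditions and call alleles:

```text
$ bewindow compare demo/run.yaml
demo_cbe: fold=7.23 p=3.7e-09 (n_out=4, n_on=4)

$ bewindow alleles demo/run.yaml
demo_cbe/ctrl: perfect-of-total=0.0530
demo_cbe/g8p: perfect-of-total=0.0852
```

The fold of 7.23 (p = 3.7×10⁻⁹) recovers the constructed 9-fold
preference of inhibition for out-of-window positions at this modest
2,000-read depth: the inhibitor suppressed bystander cytidine editing
~7-fold more strongly than on-target editing, and accordingly the
perfectly edited fraction of the population rose from 5.3% to 8.5%.
Per-position detail lands in `out/demo_cbe.inhibition.tsv` (long-format
site × position × IR heat-map table), `out/demo_cbe.comparison.json`, and
per-sample conversion-matrix and allele TSVs.  `bewindow quantify` writes
the per-position matrices alone, and every stage is importable from Python
(`bewindow.pipeline`, `bewindow.windows`, `bewindow.alleles`, ...).

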