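# samph

Temporal-modulation analysis of speech for cohort comparisons: the
**S**pectral-**A**mplitude **M**odulation **P**hase **H**ierarchy (S-AMPH)
measurement chain, with a ground-truth synthetic-signal generator and the
group-level statistics used to compare speakers (for example, adults with
different levels of literacy) on how rhythmically structured their speech is.

## The problem

The energy of speech rises and falls quasi-rhythmically at several nested
timescales: stressed syllables (~2 Hz, *delta*), syllables (~5 Hz, *theta*)
and phoneme-scale events (~20 Hz, *beta/low-gamma*).  How tightly these
amplitude-modulation (AM) bands are phase-aligned — and how modulation energy
distributes across rates — characterises a speaker's temporal organisation of
speech, and differs across speaking styles and speaker populations.  `samph`
measures this structure from short mono recordings:

1. z-score the segment; band-pass into 5 spectral bands
   (edges 100, 300, 700, 1750, 3900, 7250 Hz) with zero-phase FIR filters;
2. extract each band's Hilbert envelope and downsample to 1050 Hz;
3. band-pass each envelope into delta (0.9–2.5 Hz), theta (2.5–12 Hz) and
   beta/low-gamma (12–40 Hz) AM waveforms;
4. compute a 24-channel log-spaced modulation spectrum (relative power
   difference from the channel mean) and the signed area under it per AM
   band;
5. compute the n:m phase synchronisation index between nested AM bands,

   PSI = | ⟨ e^( i (n·θ₁ − θ₂) ) ⟩ |,

   with n = 2 for delta–theta and n = 3 for theta–beta/low-gamma, where θ₁,
   θ₂ are the instantaneous phases of the slower and faster AM.  PSI is 0 for
   rhythmically unrelated bands and 1 for perfect n:m locking.  Values are
   averaged over the 5 spectral bands per segment and over segments per
   participant and speech register.

Because recordings of this kind are rarely shareable, the package ships a
generator of speech-like signals with *known* AM hierarchy — band-limited
noise carriers multiplied by nested modulators whose phase coupling is
controlled by a von Mises concentration κ (expected PSI = I₁(κ)/I₀(κ)) — and
a cohort simulator that produces WAV files, a manifest and a ground-truth
table for end-to-end validation.  See `docs/methods.md` for the model,
parameter defaults and known limitations.

## Worked example

```bash
python analysis/01_simulate_cohort.py    # synthetic cohorts -> scratch/, results/
python analysis/02_analyze_segments.py   # full measurement chain -> results/
python analysis/03_cohort_statistics.py  # MANOVA / rm-ANOVA / correlations
```

`02_analyze_segments.py` analyses a reduced demo cohort (3 participants per
literacy group, 3 conversational + 3 rhythmic 10 s segments each) generated
with weak conversational coupling in the illiterate group and strong rhythmic
coupling everywhere, and prints the participant-level grand means:

```
analyzed 54 segments, 9 participants
                              psi_delta_theta  psi_theta_betagamma  theta_auc
register       group
conversational high_literate            0.886                0.599      0.050
               illiterate               0.653                0.275     -0.182
               low_literate             0.822                0.502     -0.059
rhythmic       high_literate            0.883                0.572     -0.111
               illiterate               0.901                0.551     -0.187
               low_literate             0.900                0.596     -0.065
```

The illiterate group shows markedly lower phase synchronisation than both
literate groups in conversational speech for both band pairs, and no deficit
in rhythmic speech — the qualitative pattern the cohort generator was
configured to produce.  (The theta AUC is the *signed* area of the
differenced modulation spectrum in 2.5–12 Hz: more positive means relatively
more theta-rate energy.)  `03_cohort_statistics.py` then confirms the pattern
statistically (a significant Wilks'-Λ MANOVA group effect for conversational,
none for rhythmic speech) and emits the full report as JSON and text under
`results/`.

The same machinery is scriptable through the CLI: `samph simulate`,
`samph analyze`, `samph stats` (see `samph --help`).

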