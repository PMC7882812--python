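# Worked-example call matrix: 17 regulated neuronal-guidance-cue genes with
# per-dataset direction calls across three monocyte-to-macrophage comparisons
# (one RNA-seq, two microarray). '-' = no call; significant marks calls that
# reached P < 0.05 in their source dataset (metadata only; consensus uses
# direction alone).
gene	dataset_id	call	significant
NTNG2	mono_macro_rnaseq	Down	false
NTNG2	mono_macro_microarray	Down	true
NTNG2	thp1_microarray	-	false
ADORA2B	mono_macro_rnaseq	Up	false
ADORA2B	mono_macro_microarray	-	false
ADORA2B	thp1_microarray	Up	true
EPHA1	mono_macro_rnaseq	Down	false
EPHA1	mono_macro_microarray	Down	true
EPHA1	thp1_microarray	Down	true
EPHB3	mono_macro_rnaseq	Down	false
EPHB3	mono_macro_microarray	Down	true
EPHB3	thp1_microarray	-	false
EPHB4	mono_macro_rnaseq	Down	false
EPHB4	mono_macro_microarray	Down	true
EPHB4	thp1_microarray	Down	true
SEMA3C	mono_macro_rnaseq	Up	false
SEMA3C	mono_macro_microarray	-	false
SEMA3C	thp1_microarray	Up	true
SEMA4A	mono_macro_rnaseq	Down	false
SEMA4A	mono_macro_microarray	Down	false
SEMA4A	thp1_microarray	Down	false
SEMA4B	mono_macro_rnaseq	Down	false
SEMA4B	mono_macro_microarray	Down	true
SEMA4B	thp1_microarray	-	false
SEMA4D	mono_macro_rnaseq	Down	false
SEMA4D	mono_macro_microarray	Down	true
SEMA4D	thp1_microarray	Down	true
SEMA4F	mono_macro_rnaseq	Up	false
SEMA4F	mono_macro_microarray	Up	true
SEMA4F	thp1_microarray	Up	true
SEMA6A	mono_macro_rnaseq	Down	false
SEMA6A	mono_macro_microarray	-	false
SEMA6A	thp1_microarray	Down	true
SEMA7A	mono_macro_rnaseq	Up	false
SEMA7A	mono_macro_microarray	Up	true
SEMA7A	thp1_microarray	Up	true
NRP1	mono_macro_rnaseq	Up	false
NRP1	mono_macro_microarray	Up	true
NRP1	thp1_microarray	Up	true
NRP2	mono_macro_rnaseq	Up	false
NRP2	mono_macro_microarray	Up	true
NRP2	thp1_microarray	Up	true
PLXNA1	mono_macro_rnaseq	Up	false
PLXNA1	mono_macro_microarray	Up	true
PLXNA1	thp1_microarray	Up	true
PLXNA3	mono_macro_rnaseq	Up	false
PLXNA3	mono_macro_microarray	Up	true
PLXNA3	thp1_microarray	Up	true
PLXND1	mono_macro_rnaseq	-	false
PLXND1	mono_macro_microarray	Up	true
PLXND1	thp1_microarray	Up	true
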