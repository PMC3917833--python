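# Approximate coordinates of the hypervariable regions V1-V9 on the
# S. cerevisiae 18S rRNA gene (1-based, inclusive). These defaults are
# deliberately labeled approximate: exact boundaries vary between secondary
# structure models, and users profiling their own alignment should override
# them with region definitions derived from their entropy profile.
# The eukaryote V6 is relatively conserved and is typically excluded from
# resolution analyses.
name	start	end
V1	69	109
V2	136	298
V3	474	545
V4	571	952
V5	1059	1114
V6	1149	1180
V7	1241	1294
V8	1370	1454
V9	1604	1690
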