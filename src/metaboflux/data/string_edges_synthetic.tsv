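node1	node2	combined_score
Hk1	Gapdh	912
Hk1	Pgk1	780
Hk1	Pkm	823
Gapdh	Pgk1	965
Gapdh	Pgam1	948
Gapdh	Eno1	931
Gapdh	ENSRNOG00000015290	957
Pgk1	Pgam1	953
Pgk1	Eno1	902
Pgam1	Eno1	961
Pgam1	Pkm	871
Eno1	Pkm	944
Eno1	LOC689343	836
Pkm	Pdha1	905
Pkm	LOC689343	899
ENSRNOG00000015290	Pgam1	846
ENSRNOG00000015290	Eno1	812
LOC689343	Gapdh	821
Pdha1	Aco2	878
Pdha1	Mdh2	903
Aco2	Mdh2	934
Mdh2	Atp5a1	742
Mdh2	Atp5b	719
Pdha1	Atp5a1	688
Atp5a1	Atp5b	982
Gapdh	Mdh2	764
Hk1	Atp5b	512
Eno1	Pdha1	603
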