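# Partition of the chromosome-3 pericentromeric heterochromatin interval
# (D. melanogaster, FlyBase R6 coordinates, 1-based inclusive; ? = border
# coordinate not determined).  Columns: name, chrom, start, end, markers.
eu-heterochromatin variability zone	chr3L	22267604	23151844	pICon(79D),CkII
permanent banded region (80B-C to 80D-F)	chr3L	?	?	CkII,mRps5
gap/satellite-enriched banded region	chr3L	?	?	mRps5,CG17514
satellite block region (Prodsat/Dodeca)	?	?	?	CG17514,Pzl
gap/satellite-enriched banded region (3R)	chr3R	?	?	Pzl,Gfat1
distal 3R heterochromatin border	chr3R	?	?	Gfat1,CG12581
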