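species	genus	family	listed
Diomedea exulans	Diomedea	Diomedeidae	1
Diomedea antipodensis	Diomedea	Diomedeidae	1
Diomedea amsterdamensis	Diomedea	Diomedeidae	1
Diomedea dabbenena	Diomedea	Diomedeidae	1
Diomedea epomophora	Diomedea	Diomedeidae	1
Diomedea sanfordi	Diomedea	Diomedeidae	1
Phoebastria irrorata	Phoebastria	Diomedeidae	1
Phoebastria albatrus	Phoebastria	Diomedeidae	1
Phoebastria immutabilis	Phoebastria	Diomedeidae	1
Phoebastria nigripes	Phoebastria	Diomedeidae	1
Thalassarche cauta	Thalassarche	Diomedeidae	1
Thalassarche steadi	Thalassarche	Diomedeidae	1
Thalassarche salvini	Thalassarche	Diomedeidae	1
Thalassarche eremita	Thalassarche	Diomedeidae	1
Thalassarche bulleri	Thalassarche	Diomedeidae	1
Thalassarche chrysostoma	Thalassarche	Diomedeidae	1
Thalassarche melanophris	Thalassarche	Diomedeidae	1
Thalassarche impavida	Thalassarche	Diomedeidae	1
Thalassarche carteri	Thalassarche	Diomedeidae	1
Thalassarche chlororhynchos	Thalassarche	Diomedeidae	1
Phoebetria fusca	Phoebetria	Diomedeidae	1
Phoebetria palpebrata	Phoebetria	Diomedeidae	1
Macronectes giganteus	Macronectes	Procellariidae	1
Macronectes halli	Macronectes	Procellariidae	1
Procellaria aequinoctialis	Procellaria	Procellariidae	1
Procellaria conspicillata	Procellaria	Procellariidae	1
Procellaria parkinsoni	Procellaria	Procellariidae	1
Procellaria westlandica	Procellaria	Procellariidae	1
Procellaria cinerea	Procellaria	Procellariidae	1
Ardenna creatopus	Ardenna	Procellariidae	1
Puffinus mauretanicus	Puffinus	Procellariidae	1
Ardenna carneipes	Ardenna	Procellariidae	1
Ardenna grisea	Ardenna	Procellariidae	1
Ardenna tenuirostris	Ardenna	Procellariidae	1
Pterodroma macroptera	Pterodroma	Procellariidae	1
Pterodroma solandri	Pterodroma	Procellariidae	1
Pterodroma lessonii	Pterodroma	Procellariidae	0
Pterodroma mollis	Pterodroma	Procellariidae	0
Puffinus yelkouan	Puffinus	Procellariidae	0
Sterna sp.	Sterna	Laridae	0
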