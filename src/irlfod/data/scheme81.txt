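-2.03982162990146126e-01 +9.78913126072630480e-01 +1.09712708731425131e-02
+8.48919557191703422e-01 -5.28315035514582920e-01 +1.47921826201332946e-02
+5.07453495933960164e-01 +8.60629252896686903e-01 +4.25233879517269361e-02
-9.98734714080385166e-01 -2.41974562733398464e-02 +4.40846231771460373e-02
+9.53974453460999960e-01 +2.95340954440161618e-01 +5.20236751312402670e-02
+6.55757468524891807e-01 -7.52945801900331557e-01 +5.52699002576625964e-02
-6.87007563926051223e-01 -7.24156479910401774e-01 +6.01498105746661182e-02
+2.58491248194860135e-01 +9.61339592330326842e-01 +9.49129223279119166e-02
-6.00604876526193293e-02 -9.91495796495511006e-01 +1.15450523405750460e-01
+9.54928233376638236e-01 -2.59495327624714611e-01 +1.44132730637820838e-01
-8.72902954768534634e-01 -4.65993087971158848e-01 +1.44536754908450055e-01
-9.50235277432409986e-01 +2.75448737902114160e-01 +1.45536628760883191e-01
-4.57291951626367599e-01 +8.76255920857081483e-01 +1.51853982959473749e-01
+8.11817371962257339e-01 +5.63333387055356405e-01 +1.53649111969557522e-01
-4.65073659909161392e-03 +9.85900626266901670e-01 +1.67267228636146403e-01
+4.35785287136435606e-01 -8.81386878394805451e-01 +1.82341312128861038e-01
+9.80052910260933330e-01 +3.94485873700895773e-02 +1.94782191289603196e-01
-3.57044723549306553e-01 -9.09011964204727962e-01 +2.14979799791192888e-01
-6.68090223715826825e-01 +7.06128923367963846e-01 +2.34600504173662794e-01
+6.44814097942798981e-01 +7.18853991334295062e-01 +2.59737787464526859e-01
-9.30863531352983276e-01 -2.46423246797380480e-01 +2.69756685616669545e-01
+8.39727214874602668e-01 -4.63767700705577102e-01 +2.82449507666777844e-01
+6.51291589593174902e-01 -7.01079292177437252e-01 +2.90356834610757786e-01
-8.33698825850469283e-01 +4.69371420917942928e-01 +2.90923936796235738e-01
+1.70999284917753125e-01 -9.34339102030194990e-01 +3.12681446483519754e-01
-2.54930772113356907e-01 +9.13306340923127569e-01 +3.17618999839895499e-01
-9.46160618673307141e-01 +3.11401473031838356e-02 +3.22196174554696568e-01
-5.12474012147247193e-01 -7.91464410946430608e-01 +3.33098293419409330e-01
-7.31048719178532314e-01 -5.95283914212573761e-01 +3.33473884535482767e-01
+8.82861364281346317e-01 +3.29518479189217783e-01 +3.34624241997056759e-01
+3.84998087630418151e-01 +8.52715247864591297e-01 +3.53062570347168703e-01
+8.98780662050205792e-01 -1.91069265647253850e-01 +3.94570471841992843e-01
-1.20403132499306356e-01 -9.08523453770898604e-01 +4.00110259344286845e-01
+1.22696378047398524e-01 +9.07299919365802898e-01 +4.02184603301590449e-01
-4.65639712808222861e-01 +7.74190804103968788e-01 +4.28728651592969801e-01
-8.69802475315319623e-01 +2.40945597042439064e-01 +4.30568081958249027e-01
+7.25774495041579870e-01 +5.17976679814438956e-01 +4.52715740300191405e-01
+4.21750510841507831e-01 -7.85205625735567403e-01 +4.53407798695769249e-01
+8.79660971023924376e-01 +8.06631284637596840e-02 +4.68711036528568992e-01
-7.91666560566019251e-01 -3.73149375436920838e-01 +4.83759858289839251e-01
-6.54484148834532653e-01 +5.47395208586020199e-01 +5.21544805880956419e-01
-8.35869994152579898e-01 -8.66767302338326551e-02 +5.42041047625857919e-01
+6.19589938492358772e-01 -5.67420722461889016e-01 +5.42348625737968493e-01
-3.43967036231533185e-01 -7.62618306156409353e-01 +5.47813834346326467e-01
-1.20766583779253631e-01 +8.21576993701591762e-01 +5.57159470584987271e-01
+4.80501041402410844e-01 +6.77097733976313454e-01 +5.57366493301616028e-01
-6.03058811194992828e-01 -5.66810587731013116e-01 +5.61289433248217784e-01
+7.50997445545471209e-01 -3.43278428221049148e-01 +5.64059179078102768e-01
+1.63545675366999765e-01 -8.05733596096669058e-01 +5.69250546060240392e-01
+7.66012917927385240e-01 +2.58396864637949975e-01 +5.88604510612728893e-01
+2.21568672275824136e-01 +7.74735882566872536e-01 +5.92192228697116296e-01
-7.67165553172500236e-02 -7.82149360146599415e-01 +6.18350182794927594e-01
-7.09328417279759815e-01 +2.82133392824979956e-01 +6.45951968100149543e-01
-3.19399427756832943e-01 +6.84304447084842282e-01 +6.55523782366830621e-01
+7.32714568796499099e-01 -5.65135878952057608e-02 +6.78185501951030445e-01
+4.11179470487015752e-01 -5.73564009231314009e-01 +7.08488369957135156e-01
+5.34484681859198618e-01 +4.43915402435963946e-01 +7.19211540743047051e-01
-5.03372202873056951e-01 +4.65082445253473253e-01 +7.28227124248868041e-01
-6.11673909436443841e-01 -2.93508435566358417e-01 +7.34648097231678565e-01
-6.70167775785852737e-01 +1.12149014510185639e-02 +7.42124907467527906e-01
-2.13897535537409325e-02 +6.59285072296667218e-01 +7.51588765143338500e-01
-4.04138726882667110e-01 -5.20147834564899214e-01 +7.52408213426131733e-01
+5.51726922807745823e-01 -3.55128810238453829e-01 +7.54639603246288648e-01
+2.79025083571968091e-01 +5.61302375995041070e-01 +7.79156367772206426e-01
+1.34106795341859070e-01 -5.82936282863322885e-01 +8.01374230659202547e-01
+5.68472145692154096e-01 +1.60556867425822758e-01 +8.06883456203289051e-01
-1.42819503744759602e-01 -5.68815263961482187e-01 +8.09970237005366966e-01
-5.12839626044691577e-01 +2.09291322781675726e-01 +8.32581923997054774e-01
-2.17354005756837360e-01 +4.75764316838957257e-01 +8.52294286619485253e-01
+5.10486908978169063e-01 -1.08143454068119510e-01 +8.53058092455684425e-01
-3.18547903434004687e-01 -3.41189677757868681e-01 +8.84373697601461894e-01
-4.60709345089739264e-01 -7.27004838338151521e-02 +8.84568560936524029e-01
+3.16834962939455234e-01 +3.16663157488245195e-01 +8.94058192148994735e-01
+2.87208486569109078e-01 -3.40415312561143713e-01 +8.95337199169441766e-01
+2.88697242855262028e-02 +4.24587647825367120e-01 +9.04926443604009090e-01
-2.80430570197419196e-02 -3.65140538819950178e-01 +9.30529942486142625e-01
+3.41430982714555853e-01 +3.88995388914617213e-02 +9.39101543985848441e-01
-2.45260135973516702e-01 +2.01613923718062610e-01 +9.48261193693625382e-01
-1.67210354967131186e-01 -7.08541359130401283e-02 +9.83371948255482020e-01
+1.09969487517115896e-01 -1.10012897607786903e-01 +9.87827856549490901e-01
+2.12853145199681376e-02 +1.44497598599577448e-01 +9.89276189638030989e-01
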